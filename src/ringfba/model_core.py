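"""Compartmentalized stoichiometric network data model, I/O and edit primitives.

Metabolite identifiers use bracket notation ``base[compartment]`` (e.g.
``glc[e]``, ``accoa[m]``); the base name is the compartment-free species name.
Flux units are mmol/gDCW/h throughout; the biomass reaction's flux is the
growth rate (1/h).

Sign conventions
----------------
* Negative stoichiometric coefficients mean consumption, positive production.
* Exchange reactions touch exactly one metabolite with coefficient -1, so a
  positive flux is secretion and a negative flux is uptake; medium uptake
  limits are therefore negative *lower* bounds (glucose uptake of
  4.19 mmol/gDCW/h is a lower bound of -4.19).

Every edit primitive returns a new model; the input model is never mutated.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "BiomassComponent",
    "Finding",
    "ModelError",
    "SBMLParseError",
    "DEFAULT_BALANCE_EXEMPT",
    "NEGLIGIBLE_COEFFICIENT",
    "COMPARTMENTS",
    "base_name",
    "compartment_of",
    "met_id",
    "load_sbml",
    "write_sbml",
    "sbml_string",
    "load_reaction_table",
    "validate_model",
    "apply_medium",
    "load_medium",
    "yes_medium",
    "add_biomass_component",
    "remove_biomass_component",
    "add_intercompartment_exchange",
]

#: canonical compartment tags: cytoplasm, mitochondria, nucleus, peroxisome,
#: endoplasmic reticulum, golgi, vacuole, extracellular
COMPARTMENTS = ("c", "m", "n", "x", "r", "g", "v", "e")

#: base names excluded from mass-balance validation by default (water and
#: hydroxyl are assumed to be turned over by non-enzymatic processes)
DEFAULT_BALANCE_EXEMPT = frozenset({"h2o", "oh"})

#: default biomass coefficient for components included only to couple a
#: pathway to growth; small enough to perturb the growth rate by <0.1%
NEGLIGIBLE_COEFFICIENT = 1e-6

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass")

DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)


class ModelError(ValueError):
    """Raised on violated model invariants or invalid edits."""


class SBMLParseError(ModelError):
    """Raised when an SBML document cannot be parsed into a model."""


_MET_ID_RE = re.compile(r"^(?P<base>[^\[\]]+)\[(?P<comp>[^\[\]]+)\]$")


def base_name(metabolite_id: str) -> str:
    """Compartment-free species name of ``base[comp]`` style id."""
    m = _MET_ID_RE.match(metabolite_id)
    return m.group("base") if m else metabolite_id


def compartment_of(metabolite_id: str) -> str | None:
    m = _MET_ID_RE.match(metabolite_id)
    return m.group("comp") if m else None


def met_id(base: str, compartment: str) -> str:
    return f"{base}[{compartment}]"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            comp = compartment_of(self.id)
            if comp is None:
                raise ModelError(
                    f"metabolite {self.id!r}: no compartment given and id is "
                    "not in base[comp] form"
                )
            self.compartment = comp


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_REVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_REVERSIBLE_BOUNDS[1]
    genes: frozenset[str] = frozenset()
    kind: str = "metabolic"
    subsystem: str | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items() if c != 0}
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has no nonzero coefficients")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "exchange" and len(self.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def compartments(self) -> set[str]:
        return {compartment_of(m) or "" for m in self.stoichiometry}


@dataclass
class BiomassComponent:
    metabolite_id: str
    coefficient: float | None = None  # mmol/gDCW consumed; None -> negligible


@dataclass
class MediumSpec:
    """Named exchange bounds defining a growth medium."""

    name: str
    exchange_bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for ex, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ModelError(f"medium {self.name!r}: bounds of {ex!r} unordered")


@dataclass
class Finding:
    """One validation finding; findings are reported, never raised."""

    kind: str
    members: tuple[str, ...]
    message: str


@dataclass
class MetabolicModel:
    id: str
    compartments: set[str]
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_id: str
    balance_exempt: set[str] = field(default_factory=lambda: set(DEFAULT_BALANCE_EXEMPT))
    #: analysis annotations maintained by the reconciliation loop --------
    #: reaction id -> set of reactions deleted *together* when simulating it
    deletion_overrides: dict[str, frozenset[str]] = field(default_factory=dict)
    #: reactions masked out of the in silico/in vivo comparison (but kept
    #: in the stoichiometric network)
    excluded_reactions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.check()

    # -- invariants ------------------------------------------------------
    def check(self) -> None:
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {met.id!r}: compartment {met.compartment!r} "
                    "is not declared in the model"
                )
        biomass = [r for r in self.reactions.values() if r.kind == "biomass"]
        if len(biomass) != 1:
            raise ModelError(
                f"model {self.id!r} must have exactly one biomass reaction, "
                f"found {len(biomass)}"
            )
        if self.objective_id not in self.reactions:
            raise ModelError(f"no biomass reaction: objective {self.objective_id!r} absent")
        if self.reactions[self.objective_id].kind != "biomass":
            raise ModelError(f"objective {self.objective_id!r} is not the biomass reaction")
        for rxn in self.reactions.values():
            for m in rxn.stoichiometry:
                if m not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references undeclared metabolite {m!r}"
                    )

    # -- views -----------------------------------------------------------
    @property
    def biomass(self) -> Reaction:
        return self.reactions[self.objective_id]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes
        return out

    def reactions_of_gene(self, gene: str) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if gene in r.genes)

    def exchange_for(self, base: str) -> str | None:
        """Exchange reaction id moving the given base metabolite, if any."""
        for r in self.exchanges():
            (m,) = r.stoichiometry
            if base_name(m) == base:
                return r.id
        return None

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- canonical serialization (used for replay/identity checks) -------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "compartments": sorted(self.compartments),
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment, "formula": m.formula}
                for m in sorted(self.metabolites.values(), key=lambda m: m.id)
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "genes": sorted(r.genes),
                    "kind": r.kind,
                    "subsystem": r.subsystem,
                    "provenance": r.provenance,
                }
                for r in sorted(self.reactions.values(), key=lambda r: r.id)
            ],
            "objective_id": self.objective_id,
            "balance_exempt": sorted(self.balance_exempt),
            "deletion_overrides": {
                k: sorted(v) for k, v in sorted(self.deletion_overrides.items())
            },
            "excluded_reactions": sorted(self.excluded_reactions),
        }

    def canonical_json(self) -> bytes:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1).encode()

    def structurally_equal(self, other: "MetabolicModel") -> bool:
        return self.canonical_json() == other.canonical_json()


def model_from_dict(data: Mapping) -> MetabolicModel:
    return MetabolicModel(
        id=data["id"],
        compartments=set(data["compartments"]),
        metabolites={
            m["id"]: Metabolite(m["id"], m.get("name", ""), m["compartment"], m.get("formula"))
            for m in data["metabolites"]
        },
        reactions={
            r["id"]: Reaction(
                id=r["id"],
                stoichiometry=dict(r["stoichiometry"]),
                name=r.get("name", ""),
                lower_bound=r["lower_bound"],
                upper_bound=r["upper_bound"],
                genes=frozenset(r.get("genes", ())),
                kind=r.get("kind", "metabolic"),
                subsystem=r.get("subsystem"),
                provenance=r.get("provenance"),
            )
            for r in data["reactions"]
        },
        objective_id=data["objective_id"],
        balance_exempt=set(data.get("balance_exempt", DEFAULT_BALANCE_EXEMPT)),
        deletion_overrides={
            k: frozenset(v) for k, v in data.get("deletion_overrides", {}).items()
        },
        excluded_reactions=set(data.get("excluded_reactions", ())),
    )


# ---------------------------------------------------------------------------
# reaction-table I/O
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "->", "=>")
_TERM_RE = re.compile(r"^(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(?P<met>\S+)$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``'1 A[c] + 2 B[c] -> 1 C[m]'`` into a stoichiometry map.

    Returns (stoichiometry, reversible). An empty side (``'glc[e] <=> '``)
    is allowed, which is how exchange rows are written.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelError(f"equation {text!r}: no reaction arrow found")
    lhs, rhs = text.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ModelError(f"equation {text!r}: cannot parse term {term!r}")
            coef = float(m.group("coef")) if m.group("coef") else 1.0
            mid = m.group("met")
            if compartment_of(mid) is None:
                raise ModelError(
                    f"equation {text!r}: metabolite {mid!r} lacks a [compartment] tag"
                )
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    if not stoich:
        raise ModelError(f"equation {text!r} is empty")
    return stoich, reversible


TABLE_COLUMNS = ("id", "equation", "lower_bound", "upper_bound", "genes", "kind")


def load_reaction_table(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Load a model from a plain TSV reaction table.

    Columns: ``id  equation  lower_bound  upper_bound  genes  kind``.
    Gene lists are comma- or semicolon-separated; empty bounds fall back to
    the defaults implied by the arrow (reversible arrows allow negative flux).
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"{path}: missing columns {missing}")

    reactions: dict[str, Reaction] = {}
    metabolites: dict[str, Metabolite] = {}
    for idx, row in df.iterrows():
        rid = row["id"].strip()
        if not rid:
            raise ModelError(f"{path} row {idx + 2}: empty reaction id")
        if rid in reactions:
            raise ModelError(f"{path} row {idx + 2}: duplicate reaction id {rid!r}")
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ModelError as exc:
            raise ModelError(f"{path} row {idx + 2}: {exc}") from exc
        default = DEFAULT_REVERSIBLE_BOUNDS if reversible else DEFAULT_IRREVERSIBLE_BOUNDS
        lo = float(row["lower_bound"]) if row["lower_bound"].strip() else default[0]
        hi = float(row["upper_bound"]) if row["upper_bound"].strip() else default[1]
        genes = frozenset(g.strip() for g in re.split(r"[,;]", row["genes"]) if g.strip())
        kind = row["kind"].strip() or "metabolic"
        reactions[rid] = Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lo, upper_bound=hi,
            genes=genes, kind=kind,
        )
        for m in stoich:
            metabolites.setdefault(m, Metabolite(m, base_name(m), compartment_of(m) or ""))

    biomass = [r.id for r in reactions.values() if r.kind == "biomass"]
    if len(biomass) != 1:
        raise ModelError(f"{path}: expected exactly one biomass row, found {len(biomass)}")
    return MetabolicModel(
        id=model_id or path.stem,
        compartments={m.compartment for m in metabolites.values()},
        metabolites=metabolites,
        reactions=reactions,
        objective_id=biomass[0],
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for elem, n in _FORMULA_RE.findall(formula):
        if elem:
            out[elem] = out.get(elem, 0) + (int(n) if n else 1)
    return out


def validate_model(model: MetabolicModel) -> list[Finding]:
    """Curation pass: typed findings, empty for a clean model.

    Mass balance is checked per element only for internal (non-exchange,
    non-biomass) reactions whose non-exempt metabolites all carry formulas;
    balance-exempt base names (water, hydroxyl by default) never contribute
    and are never flagged.
    """
    findings: list[Finding] = []

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        if rxn.lower_bound > rxn.upper_bound:  # unreachable via Reaction, kept for safety
            findings.append(Finding("bound_violation", (rxn.id,), "lower bound > upper bound"))
        if rxn.kind in ("exchange", "biomass"):
            continue
        mets = [
            model.metabolites[m]
            for m in rxn.stoichiometry
            if base_name(m) not in model.balance_exempt
        ]
        if not mets or any(m.formula is None for m in mets):
            continue
        balance: dict[str, float] = {}
        for m in mets:
            counts = parse_formula(m.formula or "")
            for elem, n in counts.items():
                balance[elem] = balance.get(elem, 0.0) + n * rxn.stoichiometry[m.id]
        bad = sorted(e for e, v in balance.items() if abs(v) > 1e-9)
        if bad:
            findings.append(
                Finding(
                    "element_imbalance",
                    (rxn.id,),
                    f"reaction {rxn.id} unbalanced in {', '.join(bad)}",
                )
            )

    used = {m for r in model.reactions.values() for m in r.stoichiometry}
    for mid in sorted(set(model.metabolites) - used):
        findings.append(Finding("unused_metabolite", (mid,), f"metabolite {mid} used by no reaction"))
    return findings


# ---------------------------------------------------------------------------
# medium handling
# ---------------------------------------------------------------------------

def apply_medium(
    model: MetabolicModel,
    medium: MediumSpec,
    default_bounds: tuple[float, float] = (0.0, 1000.0),
) -> MetabolicModel:
    """Return a copy with exchange bounds set from the medium.

    Exchanges not listed by the medium get ``default_bounds`` — secretion
    open, uptake closed. Unknown exchange ids in the medium are an error.
    """
    known = {r.id for r in model.exchanges()}
    unknown = sorted(set(medium.exchange_bounds) - known)
    if unknown:
        raise ModelError(f"medium {medium.name!r} references absent exchanges: {unknown}")
    out = model.copy()
    for r in out.exchanges():
        lo, hi = medium.exchange_bounds.get(r.id, default_bounds)
        r.lower_bound, r.upper_bound = float(lo), float(hi)
    return out


def load_medium(path: str | Path, name: str | None = None) -> MediumSpec:
    """Read a medium from YAML ``{exchange_id: [lower, upper], ...}`` or a
    3-column TSV (exchange id, lower, upper)."""
    path = Path(path)
    bounds: dict[str, tuple[float, float]] = {}
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        items = data.get("exchange_bounds", data) if isinstance(data, dict) else {}
        for ex, b in items.items():
            bounds[str(ex)] = (float(b[0]), float(b[1]))
        name = name or (data.get("name") if isinstance(data, dict) else None)
    else:
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ModelError(f"{path} line {ln}: expected 3 tab-separated fields")
            bounds[parts[0]] = (float(parts[1]), float(parts[2]))
    return MediumSpec(name=name or path.stem, exchange_bounds=bounds)


def _yes_preset() -> dict:
    text = resources.files("ringfba.data").joinpath("yes_medium.yaml").read_text()
    return yaml.safe_load(text)


def yes_medium(
    model: MetabolicModel,
    glucose_uptake: float = 4.19,
    unconstrained: float = 1000.0,
) -> MediumSpec:
    """Build the rich YES medium for a given model.

    Glucose uptake is capped at the measured rate (default 4.19
    mmol/gDCW/h); the five supplements (adenine, histidine, leucine, uracil,
    lysine), an editable yeast-extract nutrient list (amino acids,
    nucleobases, vitamins) and iron are left unconstrained. Preset nutrients
    lacking an exchange in the model are simply not in the returned spec;
    a model without a glucose exchange is an error.
    """
    preset = _yes_preset()
    open_bases = set(preset["supplements"]) | set(preset["yeast_extract"]) | set(preset["minerals"])
    glc_base = preset["glucose"]
    bounds: dict[str, tuple[float, float]] = {}
    glc_ex = model.exchange_for(glc_base)
    if glc_ex is None:
        raise ModelError(f"model {model.id!r} has no exchange for {glc_base!r}")
    bounds[glc_ex] = (-float(glucose_uptake), unconstrained)
    for r in model.exchanges():
        (m,) = r.stoichiometry
        if base_name(m) in open_bases:
            bounds[r.id] = (-unconstrained, unconstrained)
    return MediumSpec(name="YES", exchange_bounds=bounds)


# ---------------------------------------------------------------------------
# edit primitives
# ---------------------------------------------------------------------------

def add_biomass_component(
    model: MetabolicModel, component: BiomassComponent
) -> MetabolicModel:
    """Return a copy whose biomass reaction also consumes the component.

    With no coefficient given the negligible default (1e-6 mmol/gDCW) is
    used, which couples the producing pathway to growth while perturbing the
    unedited model's growth rate by well under 0.1%.
    """
    mid = component.metabolite_id
    if mid not in model.metabolites:
        raise ModelError(f"metabolite {mid!r} not in model")
    coef = NEGLIGIBLE_COEFFICIENT if component.coefficient is None else float(component.coefficient)
    if coef <= 0:
        raise ModelError("biomass component coefficient must be positive")
    out = model.copy()
    bm = out.biomass
    if mid in bm.stoichiometry:
        raise ModelError(
            f"{mid!r} already in the biomass reaction; remove it first to replace"
        )
    bm.stoichiometry[mid] = -coef
    return out


def remove_biomass_component(model: MetabolicModel, metabolite_id: str) -> MetabolicModel:
    out = model.copy()
    if metabolite_id not in out.biomass.stoichiometry:
        raise ModelError(f"{metabolite_id!r} not in the biomass reaction")
    del out.biomass.stoichiometry[metabolite_id]
    return out


def add_intercompartment_exchange(
    model: MetabolicModel, base: str, comp_a: str, comp_b: str
) -> tuple[MetabolicModel, str]:
    """Add a reversible transport ``base[comp_a] <=> base[comp_b]``.

    The missing counterpart metabolite is created if needed. This is a pure
    relaxation: the maximal growth rate after the addition is never lower
    than before.
    """
    if comp_a == comp_b:
        raise ModelError("intercompartment exchange needs two distinct compartments")
    ma, mb = met_id(base, comp_a), met_id(base, comp_b)
    if ma not in model.metabolites and mb not in model.metabolites:
        raise ModelError(f"{base!r} exists in neither {comp_a!r} nor {comp_b!r}")
    out = model.copy()
    for comp, m in ((comp_a, ma), (comp_b, mb)):
        if m not in out.metabolites:
            template = out.metabolites.get(ma if m == mb else mb)
            out.metabolites[m] = Metabolite(
                m, base, comp, template.formula if template else None
            )
            out.compartments.add(comp)
    rid = f"T_{base}_{comp_a}_{comp_b}"
    if rid in out.reactions:
        raise ModelError(f"transport {rid!r} already present")
    out.reactions[rid] = Reaction(
        id=rid,
        name=f"{base} transport {comp_a}<->{comp_b}",
        stoichiometry={ma: -1.0, mb: 1.0},
        lower_bound=DEFAULT_REVERSIBLE_BOUNDS[0],
        upper_bound=DEFAULT_REVERSIBLE_BOUNDS[1],
        kind="transport",
        provenance="RING-added",
    )
    return out, rid


# SBML I/O lives in a sibling module to keep libsbml plumbing separate.
def load_sbml(path: str | Path) -> MetabolicModel:
    from . import io_sbml

    return io_sbml.load_sbml(path)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    from . import io_sbml

    io_sbml.write_sbml(model, path)


def sbml_string(model: MetabolicModel) -> str:
    from . import io_sbml

    return io_sbml.sbml_string(model)
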