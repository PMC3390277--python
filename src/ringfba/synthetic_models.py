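"""Deterministic toy models with planted, ground-truth-labelled defects.

The core model is a two-compartment (cytoplasm/mitochondria, plus the
extracellular space) caricature of sugar catabolism: a glucose exchange and
transporter, a lumped glycolysis step (glc -> 2 pyr), a fermentation branch
(pyr -> acald -> ethanol, so one glucose yields at most 2 ethanol + 2 CO2),
a lactate branch, and a lumped mitochondrial oxidation/TCA cycle (pyr ->
acetyl-CoA + CO2; acetyl-CoA + oaa -> cit -> oaa + 2 CO2) giving full
oxidation of glucose to 6 CO2. Biomass consumes cytosolic pyruvate and
mitochondrial acetyl-CoA. Metabolites carry carbon-only pseudo-formulas so
that element-balance validation has exact expected answers. Redox and
energy cofactors are deliberately left out: yields then have closed-form
carbon-balance values, and the model stays small enough for exhaustive LP
cross-checks.

``plant_defects`` inserts network defects of each reconcilable discrepancy
class — compartment duplicates, orphan reactions, dead-end chains,
multi-reaction genes, multi-gene reactions and a missing intercompartment
transporter — and records per defect the members, the phenotype the matching
library must report, and the confusion label the defect produces before
reconciliation. ``make_phenotype_library`` then builds a library in which
every non-defect gene is observed as predicted (true by construction) and
every defect gene is observed so that the pre-reconciliation prediction is
false. That assignment is the test harness's contract: it guarantees each
planted defect shows up as exactly the intended FP/FN.

Everything here is deterministic given (seed, spec); the random generators
at the bottom produce small random systems/models for property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fba_engine import StoichiometricSystem
from .knockout_sim import LETHAL, VIABLE, essentiality_scan
from .model_core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    met_id,
    write_sbml,
)
from .phenotype_eval import PhenotypeRecord, write_phenotype_library

__all__ = [
    "DefectSpec",
    "DEFECT_KINDS",
    "make_core_model",
    "plant_defects",
    "make_phenotype_library",
    "emit_fixture",
    "random_system",
    "random_growth_model",
]

DEFECT_KINDS = (
    "compartment_duplicate",
    "orphan",
    "dead_end",
    "multi_reaction_gene",
    "multi_gene_reaction",
    "missing_transporter",
)


@dataclass(frozen=True)
class DefectSpec:
    kind: str
    count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ModelError(f"unknown defect kind {self.kind!r}")
        if self.count < 1:
            raise ModelError("defect count must be >= 1")


def _met(base: str, comp: str, formula: str) -> Metabolite:
    return Metabolite(met_id(base, comp), base, comp, formula)


def make_core_model(glucose_uptake: float = 10.0) -> MetabolicModel:
    """Clean growing core model (closed-form yields: ethanol 2, lactate 2,
    CO2 6 per glucose)."""
    mets = [
        _met("glc", "e", "C6"), _met("glc", "c", "C6"),
        _met("pyr", "c", "C3"), _met("pyr", "m", "C3"),
        _met("acald", "c", "C2"), _met("etoh", "c", "C2"), _met("etoh", "e", "C2"),
        _met("lac", "c", "C3"), _met("lac", "e", "C3"),
        _met("co2", "c", "C1"), _met("co2", "m", "C1"), _met("co2", "e", "C1"),
        _met("accoa", "m", "C2"), _met("oaa", "m", "C4"), _met("cit", "m", "C6"),
    ]

    def rxn(rid, eq, gene=None, kind="metabolic", lo=0.0, hi=1000.0):
        from .model_core import parse_equation

        stoich, _ = parse_equation(eq)
        return Reaction(
            id=rid, stoichiometry=stoich, name=rid, lower_bound=lo, upper_bound=hi,
            genes=frozenset() if gene is None else frozenset({gene}), kind=kind,
        )

    reactions = [
        rxn("EX_glc", "glc[e] -> ", kind="exchange", lo=-glucose_uptake),
        rxn("EX_etoh", "etoh[e] -> ", kind="exchange"),
        rxn("EX_lac", "lac[e] -> ", kind="exchange"),
        rxn("EX_co2", "co2[e] -> ", kind="exchange"),
        rxn("GLCt", "glc[e] -> glc[c]", "g_glct", "transport"),
        rxn("GLY", "glc[c] -> 2 pyr[c]", "g_gly"),
        rxn("PDC", "pyr[c] -> acald[c] + co2[c]", "g_pdc"),
        rxn("ADH", "acald[c] -> etoh[c]", "g_adh"),
        rxn("LDH", "pyr[c] -> lac[c]", "g_ldh"),
        rxn("ETOHt", "etoh[c] -> etoh[e]", "g_etoht", "transport"),
        rxn("LACt", "lac[c] -> lac[e]", "g_lact", "transport"),
        rxn("CO2tc", "co2[c] -> co2[e]", "g_co2tc", "transport"),
        rxn("PYRtm", "pyr[c] -> pyr[m]", "g_pyrtm", "transport"),
        rxn("CO2tm", "co2[m] <=> co2[c]", "g_co2tm", "transport", lo=-1000.0),
        rxn("PDH", "pyr[m] -> accoa[m] + co2[m]", "g_pdh"),
        rxn("CS", "accoa[m] + oaa[m] -> cit[m]", "g_cs"),
        rxn("CITL", "cit[m] -> oaa[m] + 2 co2[m]", "g_citl"),
        rxn("BIOMASS", "pyr[c] + accoa[m] -> ", kind="biomass"),
    ]
    return MetabolicModel(
        id="core",
        compartments={"e", "c", "m"},
        metabolites={m.id: m for m in mets},
        reactions={r.id: r for r in reactions},
        objective_id="BIOMASS",
    )


# ---------------------------------------------------------------------------
# defect planting
# ---------------------------------------------------------------------------

def _add(model: MetabolicModel, mets: list[Metabolite], rxns: list[Reaction]) -> None:
    for m in mets:
        model.metabolites.setdefault(m.id, m)
        model.compartments.add(m.compartment)
    for r in rxns:
        if r.id in model.reactions:
            raise ModelError(f"defect reaction id {r.id!r} collides")
        model.reactions[r.id] = r


def plant_defects(
    model: MetabolicModel, specs: list[DefectSpec]
) -> tuple[MetabolicModel, list[dict]]:
    """Insert the requested defects; returns (model, ground-truth table).

    Each ground-truth entry lists the defect kind, the planted reaction
    members, the per-gene phenotypes the library must contain, and the
    confusion label expected from the pre-reconciliation comparison.
    """
    out = model.copy()
    truth: list[dict] = []
    kinds = [s.kind for s in specs]
    if kinds.count("missing_transporter") and any(
        s.kind == "missing_transporter" and s.count > 1 for s in specs
    ):
        raise ModelError("only one missing_transporter defect is supported")

    for spec in specs:
        for i in range(1, spec.count + 1):
            if spec.kind == "compartment_duplicate":
                rid = f"GLY_n{i}"
                _add(
                    out,
                    [_met("glc", "n", "C6"), _met("pyr", "n", "C3")],
                    [Reaction(rid, {met_id("glc", "n"): -1.0, met_id("pyr", "n"): 2.0},
                              name=rid, lower_bound=0.0, upper_bound=1000.0,
                              genes=frozenset({"g_gly"}))],
                )
                truth.append({
                    "kind": spec.kind, "members": [rid],
                    "library": {"g_gly": LETHAL}, "expected_label": "FP",
                })
            elif spec.kind == "orphan":
                rid, gene = f"ORPH{i}", f"g_orph{i}"
                _add(
                    out,
                    [_met(f"trna{i}", "c", "C10"), _met(f"aatrna{i}", "c", "C13")],
                    [Reaction(rid, {met_id("pyr", "c"): -1.0,
                                    met_id(f"trna{i}", "c"): -1.0,
                                    met_id(f"aatrna{i}", "c"): 1.0},
                              name=rid, lower_bound=0.0, upper_bound=1000.0,
                              genes=frozenset({gene}))],
                )
                truth.append({
                    "kind": spec.kind, "members": [rid],
                    "library": {gene: LETHAL}, "expected_label": "FP",
                })
            elif spec.kind == "dead_end":
                r1, r2 = f"DE{i}a", f"DE{i}b"
                g1, g2 = f"g_de{i}a", f"g_de{i}b"
                _add(
                    out,
                    [_met(f"hemeA{i}", "c", "C3"), _met(f"heme{i}", "c", "C3")],
                    [
                        Reaction(r1, {met_id("pyr", "c"): -1.0,
                                      met_id(f"hemeA{i}", "c"): 1.0},
                                 name=r1, lower_bound=0.0, upper_bound=1000.0,
                                 genes=frozenset({g1})),
                        Reaction(r2, {met_id(f"hemeA{i}", "c"): -1.0,
                                      met_id(f"heme{i}", "c"): 1.0},
                                 name=r2, lower_bound=0.0, upper_bound=1000.0,
                                 genes=frozenset({g2})),
                    ],
                )
                truth.append({
                    "kind": spec.kind, "members": [r1, r2],
                    "library": {g1: LETHAL, g2: LETHAL}, "expected_label": "FP",
                    "terminal": met_id(f"heme{i}", "c"),
                })
            elif spec.kind == "multi_reaction_gene":
                ra, rb, gene = f"MRG{i}a", f"MRG{i}b", f"g_mrg{i}"
                mrg = met_id(f"mrg{i}", "c")
                _add(
                    out,
                    [_met(f"mrg{i}", "c", "C3")],
                    [
                        Reaction(ra, {met_id("pyr", "c"): -1.0, mrg: 1.0},
                                 name=ra, lower_bound=0.0, upper_bound=1000.0,
                                 genes=frozenset({gene})),
                        Reaction(rb, {met_id("lac", "c"): -1.0, mrg: 1.0},
                                 name=rb, lower_bound=0.0, upper_bound=1000.0,
                                 genes=frozenset({gene})),
                    ],
                )
                out.biomass.stoichiometry[mrg] = -1.0
                truth.append({
                    "kind": spec.kind, "members": [ra, rb],
                    "library": {gene: LETHAL}, "expected_label": "FP",
                })
            elif spec.kind == "multi_gene_reaction":
                targets = ["GLCt", "GLY"]
                if i > len(targets):
                    raise ModelError(
                        "at most two multi_gene_reaction defects are supported"
                    )
                rid = targets[i - 1]
                aux = f"g_aux{i}"
                rxn = out.reactions[rid]
                main_gene = next(iter(rxn.genes))
                rxn.genes = rxn.genes | {aux}
                truth.append({
                    "kind": spec.kind, "members": [rid],
                    "library": {main_gene: LETHAL, aux: VIABLE},
                    "expected_label": "FN",
                })
            elif spec.kind == "missing_transporter":
                rid, gene = f"ACS{i}", "g_acs"
                accoa_c = met_id("accoa", "c")
                _add(
                    out,
                    [_met("accoa", "c", "C2")],
                    [Reaction(rid, {met_id("pyr", "c"): -1.0, accoa_c: 1.0,
                                    met_id("co2", "c"): 1.0},
                              name=rid, lower_bound=0.0, upper_bound=1000.0,
                              genes=frozenset({gene}))],
                )
                # re-point the acetyl-CoA demand of biomass to the cytosol:
                # the planted sole source (ACS) becomes essential in silico
                # while the library reports its gene viable
                bm = out.biomass.stoichiometry
                bm.pop(met_id("accoa", "m"), None)
                bm[accoa_c] = -1.0
                truth.append({
                    "kind": spec.kind, "members": [rid],
                    "library": {gene: VIABLE}, "expected_label": "FN",
                    "precursor": accoa_c,
                })
    out.check()
    return out, truth


def make_phenotype_library(
    model: MetabolicModel, truth: list[dict], threshold: float = 0.10
) -> list[PhenotypeRecord]:
    """Per-gene observed phenotypes consistent with the planted truth.

    Defect genes get the phenotype that falsifies the pre-reconciliation
    prediction; every other gene is observed exactly as the (defected)
    model predicts it, so a clean model yields a zero-discrepancy library.
    """
    overrides: dict[str, str] = {}
    for entry in truth:
        overrides.update(entry["library"])
    scan = essentiality_scan(model, level="reaction", threshold=threshold)
    predicted_lethal: set[str] = set()
    for _, row in scan.iterrows():
        if row["predicted"] == LETHAL:
            predicted_lethal |= set(row["genes"])
    records = []
    for gene in sorted(model.genes()):
        observed = overrides.get(
            gene, LETHAL if gene in predicted_lethal else VIABLE
        )
        records.append(PhenotypeRecord(gene, observed, source="synthetic"))
    return records


def emit_fixture(
    directory: str | Path,
    defects: list[DefectSpec] | None = None,
    glucose_uptake: float = 10.0,
) -> dict[str, Path]:
    """Write model SBML + phenotype TSV + ground-truth JSON into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model = make_core_model(glucose_uptake)
    model, truth = plant_defects(model, defects or [])
    records = make_phenotype_library(model, truth)
    paths = {
        "model": directory / "model.sbml.xml",
        "phenotypes": directory / "phenotypes.tsv",
        "ground_truth": directory / "ground_truth.json",
    }
    write_sbml(model, paths["model"])
    write_phenotype_library(records, paths["phenotypes"])
    paths["ground_truth"].write_text(json.dumps(truth, indent=1) + "\n")
    return paths


def all_defects(count: int = 1) -> list[DefectSpec]:
    return [DefectSpec(kind, count) for kind in DEFECT_KINDS]


# ---------------------------------------------------------------------------
# randomized generators for property tests
# ---------------------------------------------------------------------------

def random_system(rng: np.random.Generator, max_reactions: int = 6) -> StoichiometricSystem:
    """Random small stoichiometric system with finite bounds (bounded LP)."""
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, 5))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    S[rng.random(size=S.shape) < 0.3] = 0.0
    lower = np.where(rng.random(n) < 0.5, 0.0, -rng.integers(1, 11, n).astype(float))
    upper = rng.integers(0, 11, n).astype(float)
    upper = np.maximum(upper, lower)  # keep ordered; may pin a flux
    c = np.zeros(n)
    c[int(rng.integers(0, n))] = 1.0
    return StoichiometricSystem(
        S, lower, upper, c,
        [f"r{j}" for j in range(n)], [f"m{i}" for i in range(m)],
    )


def random_growth_model(rng: np.random.Generator, n_steps: int | None = None) -> MetabolicModel:
    """Random linear-pathway model that always grows.

    A substrate is taken up and converted through ``n_steps`` intermediates
    to a biomass precursor; each step carries one or two parallel reactions
    (distinct genes) and random dead-end branches may hang off the chain.
    """
    n_steps = int(rng.integers(2, 5)) if n_steps is None else n_steps
    mets = [_met("s", "e", "C1")] + [
        _met(f"i{k}", "c", "C1") for k in range(n_steps + 1)
    ]
    reactions = [
        Reaction("EX_s", {met_id("s", "e"): -1.0}, lower_bound=-10.0,
                 upper_bound=1000.0, kind="exchange"),
        Reaction("UPT", {met_id("s", "e"): -1.0, met_id("i0", "c"): 1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 genes=frozenset({"g_upt"}), kind="transport"),
    ]
    gidx = 0
    for k in range(n_steps):
        n_par = 1 + int(rng.random() < 0.4)
        for p in range(n_par):
            gidx += 1
            reactions.append(Reaction(
                f"S{k}_{p}",
                {met_id(f"i{k}", "c"): -1.0, met_id(f"i{k + 1}", "c"): 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                genes=frozenset({f"g{gidx}"}),
            ))
        if rng.random() < 0.3:
            gidx += 1
            mets.append(_met(f"d{k}", "c", "C1"))
            reactions.append(Reaction(
                f"B{k}",
                {met_id(f"i{k}", "c"): -1.0, met_id(f"d{k}", "c"): 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                genes=frozenset({f"g{gidx}"}),
            ))
    reactions.append(Reaction(
        "BIOMASS", {met_id(f"i{n_steps}", "c"): -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass",
    ))
    return MetabolicModel(
        id=f"random{int(rng.integers(0, 10 ** 6))}",
        compartments={"e", "c"},
        metabolites={m.id: m for m in mets},
        reactions={r.id: r for r in reactions},
        objective_id="BIOMASS",
    )
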