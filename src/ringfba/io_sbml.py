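"""SBML reading/writing via libsbml.

Written files are SBML Level 3 Version 1 with the fbc (version 2) package:
flux bounds as shared parameters, the biomass reaction as the fbc objective
and gene sets as flat OR gene-product associations. Because SBML SIds cannot
carry the bracket notation used for metabolite ids (``glc[c]``), each element
additionally stores a small JSON payload in its notes with the original id,
reaction kind, gene set and provenance; reading one of our own files is
therefore exactly round-trip safe.

Foreign files are also accepted: Level 3 + fbc from other tools, and legacy
Level 2 files with ``GENE_ASSOCIATION`` notes and kinetic-law
``LOWER_BOUND``/``UPPER_BOUND`` parameters. Boolean gene associations are
flattened to the set of mentioned genes (with a warning), reaction kinds are
inferred (single-metabolite -> exchange, objective -> biomass,
multi-compartment -> transport), and species marked as boundary conditions
are dropped from stoichiometries.
"""

from __future__ import annotations

import html
import json
import re
import warnings
from pathlib import Path

import libsbml

from .model_core import (
    DEFAULT_BALANCE_EXEMPT,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    SBMLParseError,
    compartment_of,
)

_NOTE_RE = re.compile(r"ringfba:(\{.*\})", re.S)
_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    s = raw.replace("[", "__").replace("]", "")
    s = _SID_BAD.sub("_", s)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return prefix + s


def _notes_xml(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True)
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>ringfba:{blob}</p></body>"
    )


def _read_notes(node) -> dict:
    if node is None or not node.isSetNotes():
        return {}
    text = html.unescape(node.getNotesString())
    m = _NOTE_RE.search(text)
    if not m:
        return {}
    try:
        return json.loads(m.group(1))
    except json.JSONDecodeError:
        return {}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def sbml_string(model: MetabolicModel) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    sm.setNotes(
        _notes_xml(
            {
                "id": model.id,
                "balance_exempt": sorted(model.balance_exempt),
                "deletion_overrides": {
                    k: sorted(v) for k, v in sorted(model.deletion_overrides.items())
                },
                "excluded_reactions": sorted(model.excluded_reactions),
            }
        )
    )

    for comp in sorted(model.compartments):
        c = sm.createCompartment()
        c.setId(_sid("", comp))
        c.setConstant(True)

    met_sid: dict[str, str] = {}
    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        s = sm.createSpecies()
        sid = _sid("M_", met.id)
        met_sid[met.id] = sid
        s.setId(sid)
        s.setName(met.name or met.id)
        s.setCompartment(_sid("", met.compartment))
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        s.setInitialConcentration(0.0)
        if met.formula:
            s.getPlugin("fbc").setChemicalFormula(met.formula)
        s.setNotes(_notes_xml({"id": met.id}))

    genes = sorted(model.genes())
    gene_sid = {g: _sid("G_", g) for g in genes}
    for g in genes:
        gp = mplug.createGeneProduct()
        gp.setId(gene_sid[g])
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        r = sm.createReaction()
        r.setId(_sid("R_", rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(rxn.upper_bound)))
        for m, coef in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(met_sid[m])
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        if rxn.genes:
            gpa = rplug.createGeneProductAssociation()
            if len(rxn.genes) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(gene_sid[next(iter(rxn.genes))])
            else:
                disj = gpa.createOr()
                for g in sorted(rxn.genes):
                    ref = disj.createGeneProductRef()
                    ref.setGeneProduct(gene_sid[g])
        r.setNotes(
            _notes_xml(
                {
                    "id": rxn.id,
                    "kind": rxn.kind,
                    "genes": sorted(rxn.genes),
                    "subsystem": rxn.subsystem,
                    "provenance": rxn.provenance,
                }
            )
        )

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid("R_", model.objective_id))
    fo.setCoefficient(1.0)

    return libsbml.writeSBMLToString(doc)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(sbml_string(model))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _flatten_association(assoc, out: set[str], saw_bool: list[bool]) -> None:
    if assoc is None:
        return
    if isinstance(assoc, libsbml.GeneProductRef):
        out.add(assoc.getGeneProduct())
        return
    if isinstance(assoc, (libsbml.FbcAnd, libsbml.FbcOr)):
        if isinstance(assoc, libsbml.FbcAnd):
            saw_bool.append(True)
        for i in range(assoc.getNumAssociations()):
            _flatten_association(assoc.getAssociation(i), out, saw_bool)


_GA_RE = re.compile(r"GENE_ASSOCIATION:\s*([^<]*)", re.I)


def _legacy_genes(reaction) -> frozenset[str]:
    if not reaction.isSetNotes():
        return frozenset()
    m = _GA_RE.search(reaction.getNotesString())
    if not m:
        return frozenset()
    text = m.group(1)
    tokens = re.split(r"[()\s]+", text)
    genes = {t for t in tokens if t and t.lower() not in ("and", "or", "none")}
    if re.search(r"\b(and|or)\b", text, re.I):
        warnings.warn(
            f"reaction {reaction.getId()}: boolean gene association flattened "
            "to a plain gene set",
            stacklevel=4,
        )
    return frozenset(genes)


def _legacy_bounds(reaction) -> tuple[float | None, float | None]:
    kl = reaction.getKineticLaw()
    if kl is None:
        return None, None
    lo = hi = None
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        if p.getId().upper() == "LOWER_BOUND":
            lo = p.getValue()
        elif p.getId().upper() == "UPPER_BOUND":
            hi = p.getValue()
    return lo, hi


def load_sbml(path: str | Path) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise SBMLParseError(f"{path}: file not found")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors():
        bad = []
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                bad.append(f"line {err.getLine()}: {err.getMessage().strip()}")
        if bad:
            raise SBMLParseError(f"{path}: " + "; ".join(bad))
    sm = doc.getModel()
    if sm is None:
        raise SBMLParseError(f"{path}: no <model> element")
    mplug = sm.getPlugin("fbc")

    model_notes = _read_notes(sm)

    compartments = {sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())}

    metabolites: dict[str, Metabolite] = {}
    sid_to_id: dict[str, str] = {}
    boundary: set[str] = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        notes = _read_notes(sp)
        comp = sp.getCompartment()
        if "id" in notes:
            mid = notes["id"]
        else:
            base = re.sub(r"^M_", "", sp.getId())
            base = re.sub(rf"(__|_){re.escape(comp)}$", "", base)
            mid = f"{base}[{comp}]"
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        sid_to_id[sp.getId()] = mid
        metabolites[mid] = Metabolite(mid, sp.getName() or mid, comp, formula)
    compartments |= {m.compartment for m in metabolites.values()}

    gene_label: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    objective_rid_sid = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        aobj = mplug.getActiveObjective()
        if aobj.getNumFluxObjectives() > 0:
            objective_rid_sid = aobj.getFluxObjective(0).getReaction()

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    reactions: dict[str, Reaction] = {}
    objective_id = None
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        notes = _read_notes(sr)
        rid = notes.get("id", re.sub(r"^R_", "", sr.getId()))

        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            if ref.getSpecies() not in sid_to_id:
                raise SBMLParseError(
                    f"{path}: reaction {sr.getId()} references undeclared "
                    f"species {ref.getSpecies()!r}"
                )
            m = sid_to_id[ref.getSpecies()]
            stoich[m] = stoich.get(m, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            if ref.getSpecies() not in sid_to_id:
                raise SBMLParseError(
                    f"{path}: reaction {sr.getId()} references undeclared "
                    f"species {ref.getSpecies()!r}"
                )
            m = sid_to_id[ref.getSpecies()]
            stoich[m] = stoich.get(m, 0.0) + ref.getStoichiometry()

        rplug = sr.getPlugin("fbc")
        lo = hi = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lo = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                hi = params.get(rplug.getUpperFluxBound())
        if lo is None and hi is None:
            lo, hi = _legacy_bounds(sr)
        if lo is None:
            lo = -1000.0 if sr.getReversible() else 0.0
        if hi is None:
            hi = 1000.0

        if "genes" in notes:
            genes = frozenset(notes["genes"])
        elif rplug is not None and rplug.isSetGeneProductAssociation():
            refs: set[str] = set()
            saw_and: list[bool] = []
            _flatten_association(
                rplug.getGeneProductAssociation().getAssociation(), refs, saw_and
            )
            if saw_and:
                warnings.warn(
                    f"reaction {rid}: boolean gene association flattened to a "
                    "plain gene set",
                    stacklevel=2,
                )
            genes = frozenset(gene_label.get(r, r) for r in refs)
        else:
            genes = _legacy_genes(sr)

        if "kind" in notes:
            kind = notes["kind"]
        elif objective_rid_sid is not None and sr.getId() == objective_rid_sid:
            kind = "biomass"
        elif len(stoich) == 1:
            kind = "exchange"
        elif len({compartment_of(m) for m in stoich}) > 1:
            kind = "transport"
        else:
            kind = "metabolic"

        if objective_rid_sid is not None and sr.getId() == objective_rid_sid:
            objective_id = rid
        try:
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry=stoich,
                name=sr.getName() or rid,
                lower_bound=float(lo),
                upper_bound=float(hi),
                genes=genes,
                kind=kind,
                subsystem=notes.get("subsystem"),
                provenance=notes.get("provenance"),
            )
        except ModelError as exc:
            raise SBMLParseError(f"{path}: {exc}") from exc

    if objective_id is None:
        named = [r.id for r in reactions.values() if "biomass" in r.id.lower()
                 or "biomass" in r.name.lower()]
        if len(named) == 1:
            objective_id = named[0]
            reactions[objective_id].kind = "biomass"
        else:
            raise SBMLParseError(
                f"{path}: no biomass reaction (no fbc objective and no unique "
                "reaction named 'biomass')"
            )
    reactions[objective_id].kind = "biomass"

    return MetabolicModel(
        id=model_notes.get("id", sm.getId() or path.stem),
        compartments=compartments,
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        balance_exempt=set(model_notes.get("balance_exempt", DEFAULT_BALANCE_EXEMPT)),
        deletion_overrides={
            k: frozenset(v)
            for k, v in model_notes.get("deletion_overrides", {}).items()
        },
        excluded_reactions=set(model_notes.get("excluded_reactions", ())),
    )
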