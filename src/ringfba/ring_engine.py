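"""The RING loop: reconcile in silico knockout predictions with in vivo data.

Each false prediction from the reaction-deletion scan is assigned exactly one
diagnosis, in a fixed staged order. False positives (predicted viable,
observed lethal): compartment-duplicate instance -> orphan reaction ->
dead-end pathway member -> multi-reaction gene -> unresolved (zero wild-type
flux, or mixed viable/lethal gene assignments). False negatives (predicted
lethal, observed viable): multi-gene reaction -> sole source of a biomass
precursor with an alternative producer in another compartment -> unresolved.

Each resolvable diagnosis maps to typed, reversible model edits:

* duplicates / multi-reaction genes -> simulate all instances deleted
  simultaneously (a deletion override; stoichiometry untouched);
* orphans and multi-gene reactions -> masked out of the comparison but kept
  in the network;
* dead ends -> link the terminal metabolite cross-compartment if a consumer
  exists elsewhere, otherwise couple it to growth by adding it to the
  biomass reaction with a negligible coefficient;
* sole-precursor false negatives -> add a reversible intercompartment
  transport from a compartment holding an alternative producer.

Actions are applied tentatively, one at a time, and accepted only when they
resolve their target and do not decrease the overall accuracy of the full
re-scanned comparison; otherwise the model reverts. Iterations repeat until
no action is accepted. Everything is deterministic: targets are processed in
staged order with ties broken by sorted id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import model_core
from .fba_engine import fba, zero_flux_set
from .knockout_sim import DEFAULT_THRESHOLD, essentiality_scan
from .model_core import BiomassComponent, MetabolicModel, ModelError, base_name, compartment_of
from .net_diagnostics import (
    find_compartment_duplicates,
    find_dead_end_chains,
    find_multi_gene_reactions,
    find_multi_reaction_genes,
    find_orphan_reactions,
    producers_consumers,
)
from .phenotype_eval import ConfusionSummary, PhenotypeRecord, compare, confusion_report

__all__ = [
    "Discrepancy",
    "ReconciliationAction",
    "RingConfig",
    "RingIteration",
    "RingReport",
    "evaluate_model",
    "categorize_discrepancies",
    "propose_actions",
    "apply_action",
    "replay_actions",
    "ring_iterate",
]

FP_CATEGORIES = (
    "FP1_compartment_duplicate",
    "FP2_orphan",
    "FP3_dead_end",
    "FP4_multi_reaction_gene",
    "FP_unresolved_zero_flux",
    "FP_unresolved_mixed_genes",
    "FP_unresolved",
)
FN_CATEGORIES = (
    "FN1_multi_gene_reaction",
    "FN2_sole_precursor_source",
    "FN_unresolved",
)
#: categories processed by the action loop, in the staged order
STAGED_ORDER = (
    "FP1_compartment_duplicate",
    "FP2_orphan",
    "FP3_dead_end",
    "FP4_multi_reaction_gene",
    "FN1_multi_gene_reaction",
    "FN2_sole_precursor_source",
)

ACTION_KINDS = (
    "simultaneous_deletion_set",
    "exclude_from_analysis",
    "gap_fill_link",
    "biomass_augmentation",
    "add_intercompartment_exchange",
)


@dataclass
class Discrepancy:
    target: str  # reaction id
    genes: tuple[str, ...]
    confusion_label: str  # FP | FN
    category: str
    evidence: tuple[str, ...] = ()
    reason: str = ""

    def __post_init__(self) -> None:
        ok = FP_CATEGORIES if self.confusion_label == "FP" else FN_CATEGORIES
        if self.category not in ok:
            raise ValueError(
                f"category {self.category!r} inconsistent with label {self.confusion_label!r}"
            )
        if "unresolved" in self.category and not self.reason:
            raise ValueError(f"unresolved discrepancy for {self.target!r} needs a reason")


@dataclass
class ReconciliationAction:
    kind: str
    payload: dict
    provenance: str  # target + category this action addresses
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "payload": self.payload,
            "provenance": self.provenance,
            "note": self.note,
        }


@dataclass
class RingConfig:
    threshold: float = DEFAULT_THRESHOLD
    max_iterations: int = 10
    #: biomass coefficient for growth-coupling augmentations; None -> the
    #: negligible default (1e-6 mmol/gDCW)
    augmentation_coefficient: float | None = None


@dataclass
class RingIteration:
    index: int
    summary: ConfusionSummary  # after this iteration's accepted actions
    accepted: list[ReconciliationAction]
    rejected: list[ReconciliationAction]
    category_counts: dict[str, int]


@dataclass
class RingReport:
    initial_summary: ConfusionSummary
    iterations: list[RingIteration] = field(default_factory=list)
    unresolved: list[Discrepancy] = field(default_factory=list)

    @property
    def final_summary(self) -> ConfusionSummary:
        return self.iterations[-1].summary if self.iterations else self.initial_summary

    @property
    def accepted_actions(self) -> list[ReconciliationAction]:
        return [a for it in self.iterations for a in it.accepted]

    def accuracy_trace(self) -> list[float]:
        out = [self.initial_summary.overall_accuracy]
        out += [it.summary.overall_accuracy for it in self.iterations]
        return out

    def to_json(self) -> dict:
        return {
            "initial": confusion_report(self.initial_summary),
            "final": confusion_report(self.final_summary),
            "iterations": [
                {
                    "index": it.index,
                    "summary": confusion_report(it.summary),
                    "accepted": [a.to_dict() for a in it.accepted],
                    "rejected": [a.to_dict() for a in it.rejected],
                    "category_counts": it.category_counts,
                }
                for it in self.iterations
            ],
            "unresolved": [
                {
                    "target": d.target,
                    "label": d.confusion_label,
                    "category": d.category,
                    "reason": d.reason,
                }
                for d in self.unresolved
            ],
        }

    def actions_yaml(self) -> str:
        """Replayable patch file listing the accepted actions in order."""
        return yaml.safe_dump(
            [a.to_dict() for a in self.accepted_actions], sort_keys=False
        )

    def text_log(self) -> str:
        lines = [
            f"initial accuracy: {_fmt_acc(self.initial_summary)}",
        ]
        for it in self.iterations:
            lines.append(
                f"iteration {it.index}: accepted {len(it.accepted)}, "
                f"rejected {len(it.rejected)}, accuracy {_fmt_acc(it.summary)}"
            )
            for a in it.accepted:
                lines.append(f"  + {a.kind} [{a.provenance}] {a.payload}")
            for a in it.rejected:
                lines.append(f"  - rejected {a.kind} [{a.provenance}]")
        for d in self.unresolved:
            lines.append(f"unresolved {d.confusion_label} {d.target}: {d.category} ({d.reason})")
        return "\n".join(lines) + "\n"


def _fmt_acc(summary: ConfusionSummary) -> str:
    acc = summary.overall_accuracy
    return "n/a" if acc is None else f"{100 * acc:.1f}% ({summary.TP + summary.TN}/{summary.total})"


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_model(
    model: MetabolicModel,
    records: list[PhenotypeRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[ConfusionSummary, pd.DataFrame]:
    """Reaction-deletion scan (honoring overrides/masks) compared to the
    phenotype library."""
    scan = essentiality_scan(model, level="reaction", threshold=threshold)
    return compare(scan, records)


def _label_of(labels: pd.DataFrame, target: str) -> str:
    row = labels[labels["target"] == target]
    return row["label"].iloc[0] if len(row) else "uncompared"


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def categorize_discrepancies(
    model: MetabolicModel,
    labels: pd.DataFrame,
    records: list[PhenotypeRecord] | None = None,
) -> list[Discrepancy]:
    """Assign exactly one staged category to every FP and FN row."""
    dup_of: dict[str, tuple[str, ...]] = {}
    for f in find_compartment_duplicates(model):
        for rid in f.members:
            dup_of[rid] = f.members
    orphans = find_orphan_reactions(model)
    chain_of: dict[str, object] = {}
    for ch in find_dead_end_chains(model):
        for rid in ch.reactions:
            chain_of[rid] = ch
    multi_rxn = find_multi_reaction_genes(model)
    multi_gene = find_multi_gene_reactions(model, records)
    try:
        zeros = zero_flux_set(model)
    except ValueError:
        zeros = set()

    out: list[Discrepancy] = []
    for _, row in labels.iterrows():
        label = row["label"]
        if label not in ("FP", "FN"):
            continue
        rid = row["target"]
        genes = tuple(sorted(row["genes"].split(";"))) if row["genes"] else ()
        if label == "FP":
            if rid in dup_of:
                out.append(Discrepancy(rid, genes, "FP", "FP1_compartment_duplicate",
                                       evidence=dup_of[rid]))
            elif rid in orphans:
                out.append(Discrepancy(rid, genes, "FP", "FP2_orphan", evidence=(rid,)))
            elif rid in chain_of:
                ch = chain_of[rid]
                out.append(Discrepancy(rid, genes, "FP", "FP3_dead_end",
                                       evidence=ch.reactions))
            elif any(g in multi_rxn for g in genes):
                ev = tuple(sorted({r for g in genes for r in multi_rxn.get(g, ())}))
                out.append(Discrepancy(rid, genes, "FP", "FP4_multi_reaction_gene",
                                       evidence=ev))
            elif rid in zeros:
                out.append(Discrepancy(
                    rid, genes, "FP", "FP_unresolved_zero_flux", evidence=(rid,),
                    reason="carries no flux in any optimal wild-type distribution; "
                           "likely missing regulatory information",
                ))
            elif rid in multi_gene and multi_gene[rid]["tag"] == "mixed":
                out.append(Discrepancy(
                    rid, genes, "FP", "FP_unresolved_mixed_genes", evidence=genes,
                    reason="both viable and lethal genes assigned; needs per-gene "
                           "characterization",
                ))
            else:
                out.append(Discrepancy(
                    rid, genes, "FP", "FP_unresolved", evidence=(rid,),
                    reason="no structural diagnosis matched",
                ))
        else:
            if len(genes) >= 2:
                tag = multi_gene.get(rid, {}).get("tag", "unknown")
                out.append(Discrepancy(
                    rid, genes, "FN", "FN1_multi_gene_reaction", evidence=genes,
                    reason=f"multiple associated genes ({tag}); single-gene data "
                           "cannot confirm reaction essentiality",
                ))
            else:
                payload = _sole_precursor_payload(model, rid)
                if payload is not None:
                    out.append(Discrepancy(
                        rid, genes, "FN", "FN2_sole_precursor_source",
                        evidence=(payload["metabolite"],),
                    ))
                else:
                    out.append(Discrepancy(
                        rid, genes, "FN", "FN_unresolved", evidence=(rid,),
                        reason="no alternative source for the affected biomass "
                               "precursor found in the network",
                    ))
    order = {c: i for i, c in enumerate(FP_CATEGORIES + FN_CATEGORIES)}
    out.sort(key=lambda d: (order[d.category], d.target))
    return out


def _sole_precursor_payload(model: MetabolicModel, rid: str) -> dict | None:
    """If the reaction is the sole producer of a biomass precursor and the
    same base metabolite has a producer in another compartment, return the
    transport payload reconciling it."""
    producers, _ = producers_consumers(model)
    rxn = model.reactions[rid]
    biomass_subs = set(model.biomass.substrates)
    for met in rxn.products:
        if met not in biomass_subs:
            continue
        if producers[met] - {rid}:
            continue  # not the sole source
        comp_needed = compartment_of(met)
        b = base_name(met)
        for other in sorted(model.metabolites):
            if other == met or base_name(other) != b:
                continue
            comp_alt = compartment_of(other)
            alt_producers = producers[other] - {rid}
            if alt_producers and comp_alt != comp_needed:
                return {
                    "base": b,
                    "comp_a": comp_alt,
                    "comp_b": comp_needed,
                    "metabolite": met,
                }
    return None


# ---------------------------------------------------------------------------
# actions
# ---------------------------------------------------------------------------

def propose_actions(
    disc: Discrepancy, model: MetabolicModel, config: RingConfig | None = None
) -> list[ReconciliationAction]:
    """Ordered candidate edits for one discrepancy; empty for unresolved
    categories (the reason travels on the discrepancy)."""
    config = config or RingConfig()
    prov = f"{disc.target}:{disc.category}"
    if disc.category == "FP1_compartment_duplicate":
        return [ReconciliationAction(
            "simultaneous_deletion_set",
            {"reactions": sorted(disc.evidence)},
            prov,
            note="delete all compartmental instances simultaneously",
        )]
    if disc.category == "FP4_multi_reaction_gene":
        return [ReconciliationAction(
            "simultaneous_deletion_set",
            {"reactions": sorted(disc.evidence)},
            prov,
            note="delete every reaction of the gene simultaneously",
        )]
    if disc.category == "FP2_orphan":
        return [ReconciliationAction(
            "exclude_from_analysis",
            {"reactions": [disc.target]},
            prov,
            note="orphan reaction redundant with the biomass composition; "
                 "removed from the analysis but retained in the model",
        )]
    if disc.category == "FP3_dead_end":
        chain = list(disc.evidence)
        terminal = _chain_terminal(model, chain)
        actions: list[ReconciliationAction] = []
        for payload in _gap_fill_candidates(model, terminal):
            actions.append(ReconciliationAction(
                "gap_fill_link", payload, prov,
                note="connect the dead-end terminal to a consumer in another "
                     "compartment",
            ))
        actions.append(ReconciliationAction(
            "biomass_augmentation",
            {"metabolite": terminal, "coefficient": config.augmentation_coefficient},
            prov,
            note="couple the terminal metabolite to growth with a negligible "
                 "coefficient",
        ))
        return actions
    if disc.category == "FN1_multi_gene_reaction":
        return [ReconciliationAction(
            "exclude_from_analysis",
            {"reactions": [disc.target]},
            prov,
            note="multiple genes assigned; removed from the analysis and noted "
                 "for future research",
        )]
    if disc.category == "FN2_sole_precursor_source":
        payload = _sole_precursor_payload(model, disc.target)
        if payload is None:
            return []
        payload = {k: payload[k] for k in ("base", "comp_a", "comp_b")}
        return [ReconciliationAction(
            "add_intercompartment_exchange", payload, prov,
            note="supply the precursor from a compartment with an alternative "
                 "producer",
        )]
    return []


def _chain_terminal(model: MetabolicModel, chain: list[str]) -> str:
    for ch in find_dead_end_chains(model):
        if set(chain) & set(ch.reactions):
            return ch.terminal_metabolite
    # chain no longer detected (model edited); fall back to last product
    return model.reactions[chain[-1]].products[-1]


def _gap_fill_candidates(model: MetabolicModel, terminal: str) -> list[dict]:
    _, consumers = producers_consumers(model)
    b = base_name(terminal)
    comp = compartment_of(terminal)
    out = []
    for other in sorted(model.metabolites):
        if other != terminal and base_name(other) == b and consumers[other]:
            out.append({"base": b, "comp_a": comp, "comp_b": compartment_of(other)})
    return out


def apply_action(model: MetabolicModel, action: ReconciliationAction) -> MetabolicModel:
    """Apply one action, returning a new model; the input is untouched."""
    if action.kind == "simultaneous_deletion_set":
        rxns = sorted(action.payload["reactions"])
        missing = [r for r in rxns if r not in model.reactions]
        if missing:
            raise ModelError(f"simultaneous deletion set references {missing}")
        out = model.copy()
        for rid in rxns:
            out.deletion_overrides[rid] = frozenset(rxns)
        return out
    if action.kind == "exclude_from_analysis":
        rxns = sorted(action.payload["reactions"])
        missing = [r for r in rxns if r not in model.reactions]
        if missing:
            raise ModelError(f"exclusion references {missing}")
        out = model.copy()
        out.excluded_reactions.update(rxns)
        return out
    if action.kind in ("gap_fill_link", "add_intercompartment_exchange"):
        p = action.payload
        out, _ = model_core.add_intercompartment_exchange(
            model, p["base"], p["comp_a"], p["comp_b"]
        )
        return out
    if action.kind == "biomass_augmentation":
        p = action.payload
        return model_core.add_biomass_component(
            model, BiomassComponent(p["metabolite"], p.get("coefficient"))
        )
    raise ModelError(f"unknown action kind {action.kind!r}")


def replay_actions(
    model: MetabolicModel, actions: list[ReconciliationAction]
) -> MetabolicModel:
    """Re-apply an accepted-action log to the initial model."""
    for action in actions:
        model = apply_action(model, action)
    return model


def actions_from_yaml(text: str) -> list[ReconciliationAction]:
    return [
        ReconciliationAction(d["kind"], d["payload"], d.get("provenance", ""),
                             d.get("note", ""))
        for d in yaml.safe_load(text) or []
    ]


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def ring_iterate(
    model: MetabolicModel,
    records: list[PhenotypeRecord],
    config: RingConfig | None = None,
) -> tuple[MetabolicModel, RingReport]:
    """Run the reconciliation loop to convergence.

    Per iteration: scan, compare, categorize, and walk the discrepancies in
    staged order. Each proposed action is applied tentatively and kept only
    if, after a full re-scan, it resolves its target and overall accuracy
    has not decreased. The loop stops when an iteration accepts nothing or
    ``max_iterations`` is reached. Accuracy over accepted iterations is
    non-decreasing by construction; the returned report carries every
    decision and the final unresolved discrepancies.
    """
    config = config or RingConfig()
    if not records:
        raise ValueError("phenotype library is empty")
    wt = fba(model)
    if not wt.optimal or wt.growth <= 0:
        raise ValueError("model does not grow; nothing to reconcile")

    summary, labels = evaluate_model(model, records, config.threshold)
    report = RingReport(initial_summary=summary)
    best_acc = summary.overall_accuracy or 0.0

    for index in range(1, config.max_iterations + 1):
        discrepancies = categorize_discrepancies(model, labels, records)
        counts: dict[str, int] = {}
        for d in discrepancies:
            counts[d.category] = counts.get(d.category, 0) + 1
        accepted: list[ReconciliationAction] = []
        rejected: list[ReconciliationAction] = []

        for disc in discrepancies:
            if disc.category not in STAGED_ORDER:
                continue
            if _label_of(labels, disc.target) not in ("FP", "FN"):
                continue  # already fixed earlier in this iteration
            for action in propose_actions(disc, model, config):
                try:
                    tentative = apply_action(model, action)
                except ModelError:
                    rejected.append(action)
                    continue
                try:
                    t_summary, t_labels = evaluate_model(
                        tentative, records, config.threshold
                    )
                except ValueError:
                    rejected.append(action)
                    continue
                resolved = _label_of(t_labels, disc.target) not in ("FP", "FN")
                acc = t_summary.overall_accuracy or 0.0
                if resolved and acc >= best_acc - 1e-12:
                    model = tentative
                    summary, labels = t_summary, t_labels
                    best_acc = max(best_acc, acc)
                    accepted.append(action)
                    break
                rejected.append(action)

        report.iterations.append(
            RingIteration(index, summary, accepted, rejected, counts)
        )
        if not accepted:
            break

    report.unresolved = [
        d
        for d in categorize_discrepancies(model, labels, records)
        if _label_of(labels, d.target) in ("FP", "FN")
    ]
    return model, report
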