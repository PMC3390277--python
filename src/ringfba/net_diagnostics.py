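"""Topological diagnostics feeding the reconciliation loop.

The notions below are defined graph-theoretically over the producer/consumer
structure of the network (a reversible reaction counts as both producer and
consumer of each of its metabolites; exchanges count as consumers/producers
by default):

* compartment duplicates — groups of metabolic reactions with identical
  compartment-stripped stoichiometry sitting in different compartments;
* orphan reaction — disconnected on *both* sides: some consumed metabolite
  has no producer elsewhere and some produced metabolite no consumer
  elsewhere (e.g. tRNA-charging reactions whose tRNA species occur nowhere
  else); such a reaction can never carry steady-state flux;
* dead-end chain — upstream-connected linear pathway whose terminal
  metabolite has no consumer (the terminal is the candidate for biomass
  augmentation);
* gene/reaction multiplicity maps in both directions, with multi-gene
  reactions tagged by the observed phenotypes of their genes when a
  phenotype library is supplied.

All detectors are pure functions of the model and are re-runnable: every
finding can be re-checked against the model it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import MetabolicModel, base_name
from .phenotype_eval import PhenotypeRecord

__all__ = [
    "DiagnosticFinding",
    "find_compartment_duplicates",
    "find_orphan_reactions",
    "find_dead_end_chains",
    "find_multi_reaction_genes",
    "find_multi_gene_reactions",
    "producers_consumers",
]


@dataclass
class DiagnosticFinding:
    kind: str
    members: tuple[str, ...]
    evidence: str
    extra: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"kind": self.kind, "members": list(self.members),
                "evidence": self.evidence, **self.extra}


def producers_consumers(
    model: MetabolicModel, include_exchanges: bool = True
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Metabolite -> producing / consuming reaction id sets.

    A reversible reaction (lower bound < 0) appears on both sides for each of
    its metabolites. The biomass reaction counts as a consumer.
    """
    producers: dict[str, set[str]] = {m: set() for m in model.metabolites}
    consumers: dict[str, set[str]] = {m: set() for m in model.metabolites}
    for rxn in model.reactions.values():
        if rxn.kind == "exchange" and not include_exchanges:
            continue
        for m, coef in rxn.stoichiometry.items():
            forward_produces = coef > 0
            if rxn.upper_bound > 0:
                (producers if forward_produces else consumers)[m].add(rxn.id)
            if rxn.lower_bound < 0:
                (consumers if forward_produces else producers)[m].add(rxn.id)
    return producers, consumers


def _base_signature(rxn) -> tuple:
    sig: dict[str, float] = {}
    for m, coef in rxn.stoichiometry.items():
        b = base_name(m)
        sig[b] = sig.get(b, 0.0) + coef
    return tuple(sorted((b, round(c, 9)) for b, c in sig.items() if abs(c) > 1e-12))


def find_compartment_duplicates(model: MetabolicModel) -> list[DiagnosticFinding]:
    """Groups of >=2 metabolic reactions identical after stripping
    compartment tags, localized in different compartments.

    Bounds and gene sets are ignored; only stoichiometry matters. Reactions
    with the same base stoichiometry in the *same* compartment are parallel
    isozyme routes, not compartment duplicates, and are not grouped.
    """
    groups: dict[tuple, list[str]] = {}
    for rxn in model.reactions.values():
        if rxn.kind != "metabolic":
            continue
        groups.setdefault(_base_signature(rxn), []).append(rxn.id)
    findings = []
    for sig, rids in sorted(groups.items()):
        if len(rids) < 2:
            continue
        comps = {frozenset(model.reactions[r].compartments()) for r in rids}
        if len(comps) < 2:
            continue
        findings.append(
            DiagnosticFinding(
                kind="compartment_duplicate_group",
                members=tuple(sorted(rids)),
                evidence="identical compartment-stripped stoichiometry in "
                         "distinct compartments",
                extra={"signature": [list(t) for t in sig]},
            )
        )
    return findings


def find_orphan_reactions(
    model: MetabolicModel, include_exchanges: bool = True
) -> set[str]:
    """Reactions disconnected from the network on both sides (see module
    docstring); balance-exempt metabolites never tie a reaction in."""
    producers, consumers = producers_consumers(model, include_exchanges)
    orphans: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.kind in ("exchange", "biomass"):
            continue
        ins = [m for m in rxn.substrates if base_name(m) not in model.balance_exempt]
        outs = [m for m in rxn.products if base_name(m) not in model.balance_exempt]
        unsourced = [m for m in ins if not (producers[m] - {rxn.id})]
        unconsumed = [m for m in outs if not (consumers[m] - {rxn.id})]
        if unsourced and unconsumed:
            orphans.add(rxn.id)
    return orphans


@dataclass
class DeadEndChain:
    reactions: tuple[str, ...]  # upstream -> terminal order
    terminal_metabolite: str

    def to_finding(self) -> DiagnosticFinding:
        return DiagnosticFinding(
            kind="dead_end_chain",
            members=self.reactions,
            evidence=f"terminal metabolite {self.terminal_metabolite} has no consumer",
            extra={"terminal_metabolite": self.terminal_metabolite},
        )


def find_dead_end_chains(model: MetabolicModel) -> list[DeadEndChain]:
    """Maximal linear chains ending in an unconsumed terminal metabolite.

    Starting from each non-exempt metabolite that is produced but never
    consumed, the chain is walked upstream through its sole producer while
    the linkage stays linear (single producer whose intermediate feeds only
    the chain). The chain must be connected to the network upstream —
    fully disconnected stubs are orphans, not dead ends.
    """
    producers, consumers = producers_consumers(model)
    orphans = find_orphan_reactions(model)
    chains: list[DeadEndChain] = []
    for term in sorted(model.metabolites):
        if base_name(term) in model.balance_exempt:
            continue
        if consumers[term] or not producers[term]:
            continue
        chain: list[str] = []
        met = term
        while True:
            prods = sorted(producers[met] - set(chain))
            if len(prods) != 1 or prods[0] in orphans:
                break
            rxn = model.reactions[prods[0]]
            if rxn.kind in ("exchange", "biomass"):
                break
            chain.append(rxn.id)
            # continue upstream through a substrate used only by this chain
            nxt = [
                m for m in rxn.substrates
                if base_name(m) not in model.balance_exempt
                and not (consumers[m] - set(chain))
                and producers[m]
            ]
            if len(nxt) != 1:
                break
            met = nxt[0]
        if not chain:
            continue
        upstream = model.reactions[chain[-1]]
        connected = any(
            producers[m] - set(chain)
            for m in upstream.substrates
            if base_name(m) not in model.balance_exempt
        )
        if connected:
            chains.append(DeadEndChain(tuple(reversed(chain)), term))
    return chains


def find_multi_reaction_genes(model: MetabolicModel) -> dict[str, tuple[str, ...]]:
    """Genes associated with two or more (non-exchange) reactions."""
    by_gene: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        if rxn.kind == "exchange":
            continue
        for g in rxn.genes:
            by_gene.setdefault(g, set()).add(rxn.id)
    return {
        g: tuple(sorted(rs)) for g, rs in sorted(by_gene.items()) if len(rs) >= 2
    }


def find_multi_gene_reactions(
    model: MetabolicModel, records: list[PhenotypeRecord] | None = None
) -> dict[str, dict]:
    """Reactions with two or more associated genes, tagged by the observed
    phenotypes of those genes (mixed / all_viable / all_lethal / unknown)."""
    lib = {r.gene: r.observed for r in records} if records else {}
    out: dict[str, dict] = {}
    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        if rxn.kind == "exchange" or len(rxn.genes) < 2:
            continue
        phenos = sorted({lib[g] for g in rxn.genes if g in lib})
        if not phenos:
            tag = "unknown"
        elif len(phenos) == 2:
            tag = "mixed"
        elif phenos == ["viable"]:
            tag = "all_viable"
        else:
            tag = "all_lethal"
        out[rxn.id] = {"genes": tuple(sorted(rxn.genes)), "tag": tag}
    return out
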