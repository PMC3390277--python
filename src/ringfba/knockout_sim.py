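"""Reaction- and gene-level deletion simulation and essentiality calls.

A deletion is simulated by clamping the flux of every targeted reaction to
zero and re-maximizing growth. A knockout is called lethal when the mutant
growth rate drops strictly below 10% of the wild type (the viability
threshold used throughout; exactly 10% counts as viable). Infeasible mutant
LPs are treated as zero growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fba_engine import StoichiometricSystem, build_system, solve_fba
from .model_core import MetabolicModel

__all__ = [
    "KnockoutResult",
    "DEFAULT_THRESHOLD",
    "GROWTH_ZERO",
    "classify_phenotype",
    "delete_reactions",
    "gene_knockout",
    "essentiality_scan",
]

DEFAULT_THRESHOLD = 0.10
#: growth rates below this are numerically zero
GROWTH_ZERO = 1e-9

VIABLE = "viable"
LETHAL = "lethal"


@dataclass
class KnockoutResult:
    target: str
    deleted_reactions: frozenset[str]
    mu_wt: float
    mu_ko: float
    threshold: float = DEFAULT_THRESHOLD

    @property
    def ratio(self) -> float:
        return self.mu_ko / self.mu_wt

    @property
    def predicted(self) -> str:
        return LETHAL if self.ratio < self.threshold else VIABLE


def classify_phenotype(ratio: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Lethal iff the growth ratio falls strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return LETHAL if ratio < threshold else VIABLE


def _ko_growth(system: StoichiometricSystem, cols: list[int]) -> float:
    saved = [(j, system.lower[j], system.upper[j]) for j in cols]
    for j in cols:
        system.lower[j] = 0.0
        system.upper[j] = 0.0
    try:
        mu = solve_fba(system).growth
    finally:
        for j, lo, hi in saved:
            system.lower[j] = lo
            system.upper[j] = hi
    return 0.0 if mu < GROWTH_ZERO else mu


def _wild_type(system: StoichiometricSystem) -> float:
    wt = solve_fba(system)
    if not wt.optimal or wt.Z < GROWTH_ZERO:
        raise ValueError(
            "wild-type model does not grow; the viability threshold is undefined"
        )
    return wt.Z


def delete_reactions(
    model: MetabolicModel,
    reaction_ids,
    threshold: float = DEFAULT_THRESHOLD,
    _system: StoichiometricSystem | None = None,
    _mu_wt: float | None = None,
) -> KnockoutResult:
    """Simulate the simultaneous deletion of the given reactions."""
    ids = sorted(set(reaction_ids))
    unknown = [r for r in ids if r not in model.reactions]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    system = _system if _system is not None else build_system(model)
    mu_wt = _mu_wt if _mu_wt is not None else _wild_type(system)
    mu_ko = _ko_growth(system, [system.column(r) for r in ids])
    return KnockoutResult(
        target="+".join(ids),
        deleted_reactions=frozenset(ids),
        mu_wt=mu_wt,
        mu_ko=min(mu_ko, mu_wt),
        threshold=threshold,
    )


def gene_knockout(
    model: MetabolicModel,
    gene: str,
    mode: str = "all_reactions",
    threshold: float = DEFAULT_THRESHOLD,
    _system: StoichiometricSystem | None = None,
    _mu_wt: float | None = None,
) -> KnockoutResult:
    """Simulate a single-gene knockout.

    ``all_reactions`` (default) deletes every reaction whose gene set
    contains the gene — including duplicate compartmental instances — which
    is the faithful reading of a gene deletion under flat gene sets.
    ``exact`` deletes only reactions associated with exactly this gene, a
    conservative mode for sensitivity analysis.
    """
    if mode not in ("all_reactions", "exact"):
        raise ValueError(f"unknown gene knockout mode {mode!r}")
    rxns = [
        r.id
        for r in model.reactions.values()
        if (gene in r.genes if mode == "all_reactions" else r.genes == frozenset({gene}))
    ]
    if not rxns and not model.reactions_of_gene(gene):
        raise KeyError(f"gene {gene!r} appears in no reaction")
    res = delete_reactions(model, rxns, threshold, _system=_system, _mu_wt=_mu_wt)
    return KnockoutResult(
        target=gene,
        deleted_reactions=res.deleted_reactions,
        mu_wt=res.mu_wt,
        mu_ko=res.mu_ko,
        threshold=threshold,
    )


def _scan_reactions(model: MetabolicModel) -> list[str]:
    """Deletion targets: every non-exchange, non-biomass reaction."""
    return sorted(
        r.id
        for r in model.reactions.values()
        if r.kind not in ("exchange", "biomass")
    )


def essentiality_scan(
    model: MetabolicModel,
    level: str = "reaction",
    threshold: float = DEFAULT_THRESHOLD,
    honor_overrides: bool = True,
) -> pd.DataFrame:
    """Deletion scan over the whole model.

    ``level='reaction'`` deletes each non-exchange reaction singly (the
    deletion set may be widened by a reconciliation override recorded on the
    model); ``level='gene'`` deletes, per gene, all of its reactions
    simultaneously (reactions with no gene assignment contribute no row).
    The wild type is solved once and reused. Rows are deterministically
    sorted by target.

    Columns: target, deleted_reactions, genes, mu_wt, mu_ko, ratio,
    predicted, included (False for reactions masked out of the comparison).
    """
    if level not in ("reaction", "gene"):
        raise ValueError(f"unknown scan level {level!r}")
    system = build_system(model)
    mu_wt = _wild_type(system)

    rows = []
    if level == "reaction":
        for rid in _scan_reactions(model):
            dele = {rid}
            if honor_overrides and rid in model.deletion_overrides:
                dele = set(model.deletion_overrides[rid])
            res = delete_reactions(model, dele, threshold, _system=system, _mu_wt=mu_wt)
            rows.append(
                {
                    "target": rid,
                    "deleted_reactions": ";".join(sorted(dele)),
                    "genes": frozenset(model.reactions[rid].genes),
                    "mu_wt": res.mu_wt,
                    "mu_ko": res.mu_ko,
                    "ratio": res.ratio,
                    "predicted": res.predicted,
                    "included": rid not in model.excluded_reactions,
                }
            )
    else:
        genes = sorted(
            {g for r in model.reactions.values() if r.kind not in ("exchange", "biomass")
             for g in r.genes}
        )
        for gene in genes:
            res = gene_knockout(model, gene, threshold=threshold, _system=system, _mu_wt=mu_wt)
            rows.append(
                {
                    "target": gene,
                    "deleted_reactions": ";".join(sorted(res.deleted_reactions)),
                    "genes": frozenset({gene}),
                    "mu_wt": res.mu_wt,
                    "mu_ko": res.mu_ko,
                    "ratio": res.ratio,
                    "predicted": res.predicted,
                    "included": not res.deleted_reactions <= model.excluded_reactions,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values("target").reset_index(drop=True)


def essential_sets(scan: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(essential targets, genes of essential targets) from a scan table."""
    lethal = scan[scan["predicted"] == LETHAL]
    targets = set(lethal["target"])
    genes: set[str] = set()
    for gs in lethal["genes"]:
        genes |= gs
    return targets, genes


def write_scan(scan: pd.DataFrame, path) -> None:
    out = scan.copy()
    out["genes"] = out["genes"].map(lambda gs: ";".join(sorted(gs)))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
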