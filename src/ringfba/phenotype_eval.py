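"""Confusion-matrix evaluation of knockout predictions against in vivo data.

The in vivo side is a per-gene phenotype library (gene -> viable/lethal), the
in silico side a deletion-scan table whose rows carry a target (reaction or
gene) plus the associated gene set. A prediction is counted FALSE whenever it
disagrees with the observed phenotype of ANY associated gene that has a
library record: a viable prediction with a lethal gene is a false positive
and a lethal prediction with a viable gene a false negative. Targets whose
genes all lack records (or that are masked out of the analysis) are reported
in separate buckets, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "ConfusionSummary",
    "load_phenotype_library",
    "write_phenotype_library",
    "compare",
    "metrics",
    "METRIC_NAMES",
]

VIABLE = "viable"
LETHAL = "lethal"


@dataclass(frozen=True)
class PhenotypeRecord:
    gene: str
    observed: str  # viable | lethal
    source: str = ""

    def __post_init__(self) -> None:
        if self.observed not in (VIABLE, LETHAL):
            raise ValueError(f"gene {self.gene!r}: unknown phenotype {self.observed!r}")


def load_phenotype_library(path: str | Path) -> list[PhenotypeRecord]:
    """Read a two-column TSV (gene, phenotype[, source]); duplicates rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in ("gene", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    records: list[PhenotypeRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        gene = row["gene"].strip()
        if gene in seen:
            raise ValueError(f"{path} row {idx + 2}: duplicate gene {gene!r}")
        seen.add(gene)
        phen = row["phenotype"].strip()
        if phen not in (VIABLE, LETHAL):
            raise ValueError(f"{path} row {idx + 2}: unknown phenotype {phen!r}")
        records.append(PhenotypeRecord(gene, phen, row.get("source", "")))
    return records


def write_phenotype_library(records: list[PhenotypeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"gene": r.gene, "phenotype": r.observed, "source": r.source} for r in records]
    ).sort_values("gene")
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def overall_accuracy(self):
        return self._ratio(self.TP + self.TN, self.total)

    @property
    def negative_prediction_rate(self):
        return self._ratio(self.TN, self.TN + self.FN)

    @property
    def positive_prediction_rate(self):
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def sensitivity(self):
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def specificity(self):
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def false_viable_rate(self):
        return self._ratio(self.FP, self.FP + self.FN)


METRIC_NAMES = (
    "overall_accuracy",
    "negative_prediction_rate",
    "positive_prediction_rate",
    "sensitivity",
    "specificity",
    "false_viable_rate",
)


def _round1(pct: float) -> float:
    """One decimal, half away from zero (23.45 -> 23.5)."""
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def metrics(summary: ConfusionSummary) -> dict[str, float | None]:
    """All derived rates as percentages to one decimal.

    A rate with a zero denominator is reported as None (not available),
    never as 0. Raw fractions remain available on the summary itself.
    """
    out: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        value = getattr(summary, name)
        out[name] = None if value is None else _round1(100.0 * value)
    return out


def compare(
    predictions: pd.DataFrame, records: list[PhenotypeRecord]
) -> tuple[ConfusionSummary, pd.DataFrame]:
    """Label each prediction row TP/TN/FP/FN against the phenotype library.

    ``predictions`` needs columns ``target``, ``predicted`` and ``genes``
    (a set of gene ids; for gene-level tables the singleton set). Optional
    boolean column ``included`` masks rows out of the comparison (label
    ``excluded``); rows with no recorded gene get label ``uncompared``.
    Counts conserve: TP+TN+FP+FN equals the number of compared rows.
    """
    lib = {r.gene: r.observed for r in records}
    labels = []
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for _, row in predictions.iterrows():
        genes = set(row["genes"])
        observed = sorted({lib[g] for g in genes if g in lib})
        if not row.get("included", True):
            label = "excluded"
        elif not observed:
            label = "uncompared"
        elif row["predicted"] == VIABLE:
            label = "FP" if LETHAL in observed else "TP"
        else:
            label = "FN" if VIABLE in observed else "TN"
        if label in counts:
            counts[label] += 1
        labels.append(
            {
                "target": row["target"],
                "predicted": row["predicted"],
                "observed": ";".join(observed) if observed else None,
                "genes": ";".join(sorted(genes)),
                "label": label,
            }
        )
    if sum(counts.values()) == 0:
        raise ValueError("no overlap between predictions and the phenotype library")
    table = pd.DataFrame(labels).sort_values("target").reset_index(drop=True)
    return ConfusionSummary(**counts), table


def confusion_report(summary: ConfusionSummary) -> dict:
    """JSON-ready report: counts plus derived rates (percent, one decimal)."""
    rates = metrics(summary)
    return {
        "counts": {"TP": summary.TP, "TN": summary.TN, "FP": summary.FP, "FN": summary.FN,
                   "total": summary.total},
        "rates_percent": rates,
        "raw": {
            name: (None if getattr(summary, name) is None
                   else float(getattr(summary, name)))
            for name in METRIC_NAMES
        },
    }
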