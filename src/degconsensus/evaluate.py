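"""Confusion-matrix evaluation of DEG calls against a gold standard.

The positive class is "called a DEG". Metrics are percentages:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
each times 100, reported as NA (NaN) when the denominator is zero. Direction
agreement with the gold standard does not affect the headline metrics; it is
reported separately as a direction-accuracy column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import ValidationError

__all__ = [
    "GoldStandard",
    "ConfusionMatrix",
    "PerformanceMetrics",
    "parse_gold_standard",
    "write_gold_standard",
    "gold_from_scores",
    "confusion",
    "metrics",
    "direction_accuracy",
    "evaluation_report",
]

DIRECTION_UP = "Up"
DIRECTION_DOWN = "Down"
DIRECTION_NA = "NA"


@dataclass(frozen=True)
class GoldStandard:
    """Per-gene truth labels: DEG yes/no plus direction for true DEGs."""

    is_deg: Mapping[str, bool]
    direction: Mapping[str, str]

    def __post_init__(self) -> None:
        for g, d in self.direction.items():
            if d not in (DIRECTION_UP, DIRECTION_DOWN, DIRECTION_NA):
                raise ValidationError(f"bad direction {d!r} for gene {g!r}")
            if d != DIRECTION_NA and not self.is_deg.get(g, False):
                raise ValidationError(
                    f"gene {g!r} has a direction but is not labelled DEG"
                )

    @property
    def deg_genes(self) -> frozenset[str]:
        return frozenset(g for g, v in self.is_deg.items() if v)

    def restrict(self, universe: Iterable[str]) -> "GoldStandard":
        uni = set(universe)
        return GoldStandard(
            is_deg={g: v for g, v in self.is_deg.items() if g in uni},
            direction={g: d for g, d in self.direction.items() if g in uni},
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, precision in percent (NaN when undefined)."""

    sensitivity: float
    specificity: float
    precision: float


def parse_gold_standard(path: str | Path) -> GoldStandard:
    """Read a gold-standard TSV: gene id, is_deg (DEG/not), direction."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValidationError("gold-standard table needs gene, is_deg, direction columns")
    genes = df.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene id in gold standard: {dup!r}")
    is_deg = {}
    direction = {}
    for g, flag, d in zip(genes, df.iloc[:, 1], df.iloc[:, 2]):
        flag_s = str(flag).strip()
        if flag_s not in ("DEG", "not"):
            raise ValidationError(f"is_deg must be 'DEG' or 'not', found {flag_s!r}")
        is_deg[g] = flag_s == "DEG"
        d_s = DIRECTION_NA if pd.isna(d) else str(d).strip()
        direction[g] = d_s
    return GoldStandard(is_deg=is_deg, direction=direction)


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    rows = [
        {
            "gene_id": g,
            "is_deg": "DEG" if v else "not",
            "direction": gold.direction.get(g, DIRECTION_NA),
        }
        for g, v in gold.is_deg.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def gold_from_scores(
    table: pd.DataFrame,
    lfc_col: str = "log2fc",
    p_col: str = "pvalue",
    lfc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> GoldStandard:
    """Generic gold-standard rule for a score table: |log2fc| >= lfc_cut and
    p <= p_cut marks a DEG, direction from the fold-change sign."""
    is_deg = {}
    direction = {}
    for g, row in table.iterrows():
        lfc = float(row[lfc_col])
        deg = abs(lfc) >= lfc_cut and float(row[p_col]) <= p_cut
        is_deg[str(g)] = deg
        direction[str(g)] = (
            (DIRECTION_UP if lfc > 0 else DIRECTION_DOWN) if deg else DIRECTION_NA
        )
    return GoldStandard(is_deg=is_deg, direction=direction)


def confusion(
    predicted: Iterable[str], gold: GoldStandard, universe: Iterable[str]
) -> ConfusionMatrix:
    """Tally TP/FP/FN/TN of a predicted DEG set over an evaluation universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("evaluation universe is empty")
    pred = set(predicted)
    if not pred <= uni:
        raise ValueError("predicted genes must lie inside the evaluation universe")
    true = gold.deg_genes & uni
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    def ratio(num: int, den: int) -> float:
        return num / den * 100.0 if den > 0 else float("nan")

    return PerformanceMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=ratio(cm.tp, cm.tp + cm.fp),
    )


def direction_accuracy(
    predicted_status: Mapping[str, str], gold: GoldStandard
) -> float:
    """Fraction of true-positive calls whose up/down status matches the gold
    direction (NaN if there is no true positive with a gold direction)."""
    hits = 0
    total = 0
    for g, status in predicted_status.items():
        if not gold.is_deg.get(g, False):
            continue
        want = gold.direction.get(g, DIRECTION_NA)
        if want == DIRECTION_NA:
            continue
        total += 1
        if (status == "up" and want == DIRECTION_UP) or (
            status == "down" and want == DIRECTION_DOWN
        ):
            hits += 1
    return hits / total if total else float("nan")


def evaluation_report(
    predictions: Mapping[str, frozenset[str] | set[str]],
    statuses: Mapping[str, Mapping[str, str]],
    gold: GoldStandard,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One row per method (and consensus): confusion cells + the three
    metrics + direction accuracy, over a common evaluation universe."""
    uni = set(universe)
    rows = []
    for name, pred in predictions.items():
        cm = confusion(set(pred) & uni, gold, uni)
        pm = metrics(cm)
        rows.append(
            {
                "method": name,
                "TP": cm.tp,
                "FP": cm.fp,
                "FN": cm.fn,
                "TN": cm.tn,
                "sensitivity": pm.sensitivity,
                "specificity": pm.specificity,
                "precision": pm.precision,
                "direction_accuracy": direction_accuracy(
                    {g: statuses[name][g] for g in pred if g in statuses.get(name, {})},
                    gold,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("method")
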