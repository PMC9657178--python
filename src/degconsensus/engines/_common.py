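"""Shared engine plumbing: result schema, expression filter, BH, status."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ..normalize import cpm, library_sizes
from ..tables_io import CountMatrix, Dataset

ENGINE_NAMES = ("nb_exact", "nb_wald", "noise", "eb")

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_ZERO = "zero_value"

# Pseudocount added to normalized condition means before the log2 ratio, in
# every engine, so the fold change is always finite and the status total.
LFC_PRIOR = 0.5


@dataclass(frozen=True)
class DEResult:
    """Per-method, per-gene DE summary.

    ``raw_score`` is a p-value for the frequentist engines and
    1 - probability-of-DE for the noise/eb engines; ``fdr`` is the unified
    thresholdable column (BH-adjusted p, or again 1 - probability).
    """

    method: str
    table: pd.DataFrame  # index: gene id; columns: log2fc, raw_score, fdr, status

    def __post_init__(self) -> None:
        required = {"log2fc", "raw_score", "fdr", "status"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"result table missing columns {required - set(self.table.columns)}")
        if self.method not in ENGINE_NAMES:
            raise ValueError(f"unknown method tag {self.method!r}")
        bad = self.table[["raw_score", "fdr"]].to_numpy()
        if ((bad < 0) | (bad > 1)).any() or np.isnan(bad).any():
            raise ValueError("raw_score and fdr must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def assign_status(log2fc: float | np.ndarray):
    """Regulatory status from the sign of the log2 fold change.

    ``up`` for log2fc > 0, ``down`` for < 0, ``zero_value`` for exactly 0.
    """
    arr = np.asarray(log2fc, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("log2fc must be finite")
    out = np.where(arr > 0, STATUS_UP, np.where(arr < 0, STATUS_DOWN, STATUS_ZERO))
    if np.isscalar(log2fc) or arr.ndim == 0:
        return str(out)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def expression_filter(ds: Dataset, min_cpm: float = 1.0) -> np.ndarray:
    """Boolean keep-mask: CPM > min_cpm in at least min(n_ref, n_trt) samples.

    Shared by all engines so that, given identical settings, every engine
    tests the identical gene universe.
    """
    ref_idx, trt_idx = ds.group_indices()
    min_samples = min(ref_idx.size, trt_idx.size)
    c = cpm(ds.counts)
    return (c > min_cpm).sum(axis=1) >= min_samples


def filtered_matrix(ds: Dataset, keep: np.ndarray) -> CountMatrix:
    return CountMatrix(
        gene_ids=tuple(g for g, k in zip(ds.counts.gene_ids, keep) if k),
        sample_names=ds.counts.sample_names,
        counts=ds.counts.counts[keep],
    )


def log2fc_from_means(mean_ref: np.ndarray, mean_trt: np.ndarray) -> np.ndarray:
    """log2((mean_trt + prior) / (mean_ref + prior)); always finite."""
    return np.log2((mean_trt + LFC_PRIOR) / (mean_ref + LFC_PRIOR))


def build_result(method: str, gene_ids, log2fc, raw_score, fdr) -> DEResult:
    log2fc = np.asarray(log2fc, dtype=float)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "raw_score": np.clip(np.asarray(raw_score, dtype=float), 0.0, 1.0),
            "fdr": np.clip(np.asarray(fdr, dtype=float), 0.0, 1.0),
            "status": assign_status(log2fc),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DEResult(method=method, table=table)
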