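"""Nonparametric signal-vs-noise DE engine (the noise-distribution family).

Per gene, the signal is the pair (M, D) of the log2 ratio and the absolute
difference of the condition-mean CPM values (prior 0.5). The noise
distribution pools the same pair computed between every pair of replicates
within a condition, across all genes. The probability of DE is the fraction
of noise points strictly dominated by the signal in both coordinates; the
unified score column is 1 - probability.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ..normalize import cpm
from ..tables_io import Dataset
from ._common import DEResult, build_result, expression_filter, filtered_matrix

__all__ = ["noise_test", "noise_probability"]

_CPM_PRIOR = 0.5
_CHUNK = 256


def noise_probability(
    m: np.ndarray, d: np.ndarray, noise_m: np.ndarray, noise_d: np.ndarray
) -> np.ndarray:
    """Fraction of noise points with |M0| < |M_g| and D0 < D_g, per gene.

    Strict inequalities: a gene with M = D = 0 has probability 0.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    abs_noise_m = np.abs(np.asarray(noise_m, dtype=float))
    noise_d = np.asarray(noise_d, dtype=float)
    n_noise = abs_noise_m.size
    if n_noise == 0:
        raise ValueError("empty noise distribution")
    out = np.empty(m.size)
    for lo in range(0, m.size, _CHUNK):
        hi = min(lo + _CHUNK, m.size)
        dominated = (abs_noise_m[None, :] < np.abs(m[lo:hi, None])) & (
            noise_d[None, :] < d[lo:hi, None]
        )
        out[lo:hi] = dominated.sum(axis=1) / n_noise
    return out


def noise_test(ds: Dataset) -> DEResult:
    """Probability-of-DE per gene from within-condition replicate noise."""
    ref_idx, trt_idx = ds.group_indices()
    pairs = [
        (i, j)
        for idx in (ref_idx, trt_idx)
        for i, j in combinations(idx.tolist(), 2)
    ]
    if not pairs:
        raise ValueError(
            "nonparametric engine requires replicates: at least one condition "
            "needs two or more samples"
        )
    keep = expression_filter(ds)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    cm = filtered_matrix(ds, keep)
    c = cpm(cm, prior=_CPM_PRIOR)

    mean_ref = c[:, ref_idx].mean(axis=1)
    mean_trt = c[:, trt_idx].mean(axis=1)
    m_sig = np.log2(mean_trt / mean_ref)
    d_sig = np.abs(mean_trt - mean_ref)

    noise_m = np.concatenate([np.log2(c[:, i] / c[:, j]) for i, j in pairs])
    noise_d = np.concatenate([np.abs(c[:, i] - c[:, j]) for i, j in pairs])

    prob = noise_probability(m_sig, d_sig, noise_m, noise_d)
    score = 1.0 - prob
    return build_result("noise", cm.gene_ids, m_sig, score, score)
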