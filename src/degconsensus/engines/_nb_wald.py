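"""Negative-binomial Wald test on shrunken dispersions (the Wald family).

Counts are normalized by median-of-ratios size factors; the per-gene log2
fold change of the normalized condition means is tested against zero with a
delta-method standard error under Var(count) = mu + phi * mu^2, where phi is
shrunk toward a fitted mean-dispersion trend a/mu + b.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..normalize import size_factors_mor
from ..tables_io import Dataset
from ._common import LFC_PRIOR, DEResult, bh_adjust, build_result, expression_filter, filtered_matrix, log2fc_from_means
from ._dispersion import DispersionModel, estimate_dispersion

__all__ = ["nb_wald_test", "wald_pvalue"]

_LN2 = np.log(2.0)


def wald_pvalue(log2fc, se):
    """Two-sided normal p-value for z = log2fc / se (p = 1 where se = 0 and
    the estimate is 0; p -> 0 as |log2fc| grows at fixed se)."""
    log2fc = np.asarray(log2fc, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf))
    return 2.0 * stats.norm.sf(np.abs(z))


def nb_wald_test(ds: Dataset, disp: DispersionModel | None = None) -> DEResult:
    """Wald z-test of log2fc = 0 per gene passing the expression filter."""
    keep = expression_filter(ds)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    cm = filtered_matrix(ds, keep)
    ref_idx, trt_idx = ds.group_indices()

    sf = size_factors_mor(cm).scale_factors
    norm = cm.counts / sf  # normalized counts, common scale

    if disp is None:
        disp = estimate_dispersion(norm, ref_idx, trt_idx, mode="trend")
    phi = np.asarray(disp.phi_shrunk, dtype=float)
    if phi.shape != (cm.n_genes,):
        raise ValueError("dispersion model does not match the filtered gene universe")

    mean_ref = norm[:, ref_idx].mean(axis=1)
    mean_trt = norm[:, trt_idx].mean(axis=1)
    log2fc = log2fc_from_means(mean_ref, mean_trt)

    # Var(x_i / s_i) ~= mu / s_i + phi * mu^2 (NB variance through the size
    # factor); variance of the condition mean, then of its log2, by the
    # delta method. The fold-change pseudocount keeps the denominators
    # positive for genes with an all-zero condition.
    var_log2 = np.zeros(cm.n_genes)
    for mean_k, idx in ((mean_ref, ref_idx), (mean_trt, trt_idx)):
        inv_s = (1.0 / sf[idx]).sum()
        var_mean = (mean_k * inv_s + idx.size * phi * mean_k**2) / idx.size**2
        var_log2 = var_log2 + var_mean / ((mean_k + LFC_PRIOR) * _LN2) ** 2

    se = np.sqrt(var_log2)
    pvals = wald_pvalue(log2fc, se)
    pvals = np.where(log2fc == 0, 1.0, pvals)
    return build_result("nb_wald", cm.gene_ids, log2fc, pvals, bh_adjust(pvals))
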