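"""Exact conditional negative-binomial test (the exact-test family).

Counts are first brought to a common library size using TMM effective
library sizes. For each gene the two group sums (s1, s2) are modeled as NB
with means proportional to the replicate numbers and size parameters
n_k / phi (the sum of n_k iid NB(mu, phi) variables); conditioning on the
total s = s1 + s2 gives an exact two-sided p-value as the summed probability
of all splits no more likely than the observed one (ties included, no
doubling).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..normalize import library_sizes, tmm_factors
from ..tables_io import Dataset
from ._common import DEResult, bh_adjust, build_result, expression_filter, filtered_matrix, log2fc_from_means
from ._dispersion import DispersionModel, estimate_dispersion

__all__ = ["nb_exact_test", "exact_conditional_pvalue"]

# Splits are enumerated exactly up to this total; above it the pmf is
# evaluated on a +/- 40 sd window and the negligible remaining tail mass is
# folded into the p-value.
_ENUMERATION_CAP = 10_000
_PHI_POISSON = 1e-12


def exact_conditional_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p-value for the split (s1, s2) of the total.

    Group-sum k is NB with mean s * n_k / (n1 + n2) and size n_k / phi;
    phi = 0 reduces to Poisson group sums, whose conditional distribution is
    Binomial(s, n1 / (n1 + n2)).
    """
    s = int(s1) + int(s2)
    if s == 0:
        return 1.0
    m1 = s * n1 / (n1 + n2)
    m2 = s * n2 / (n1 + n2)

    if s <= _ENUMERATION_CAP:
        a = np.arange(s + 1)
    else:
        # window carries all but ~1e-300 of the conditional mass
        sd = _split_sd(s, n1, n2, phi)
        lo = min(max(0, int(np.floor(m1 - 40 * sd))), int(s1))
        hi = max(min(s, int(np.ceil(m1 + 40 * sd))), int(s1))
        a = np.arange(lo, hi + 1)

    logp = _group_logpmf(a, m1, n1, phi) + _group_logpmf(s - a, m2, n2, phi)
    probs = np.exp(logp - logp.max())
    obs = probs[np.searchsorted(a, int(s1))]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum() / probs.sum()
    return float(min(p, 1.0))


def _group_logpmf(k: np.ndarray, mean: float, n: int, phi: float) -> np.ndarray:
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi <= _PHI_POISSON:
        return stats.poisson.logpmf(k, mean)
    r = n / phi
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def _split_sd(s: int, n1: int, n2: int, phi: float) -> float:
    # conservative spread of the conditional split: binomial sd inflated by
    # the NB overdispersion of the group sums
    frac = n1 / (n1 + n2)
    var = s * frac * (1 - frac) * (1.0 + phi * s * frac / max(n1, 1))
    return max(np.sqrt(var), 1.0)


def nb_exact_test(ds: Dataset, disp: DispersionModel | None = None) -> DEResult:
    """Run the exact conditional NB test on every gene passing the filter.

    ``disp`` overrides the internally estimated common-mode shrunken
    dispersion (shrink weight 0.7 toward the median); pass a model with zero
    dispersions to obtain the Poisson/binomial limit.
    """
    keep = expression_filter(ds)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    cm = filtered_matrix(ds, keep)
    ref_idx, trt_idx = ds.group_indices()

    factors = tmm_factors(cm)
    eff = factors.effective_sizes
    common_size = np.exp(np.mean(np.log(eff)))
    y = cm.counts * (common_size / eff)  # counts equalized to a common library

    if disp is None:
        disp = estimate_dispersion(y, ref_idx, trt_idx, mode="common")
    phi = np.asarray(disp.phi_shrunk, dtype=float)
    if phi.shape != (cm.n_genes,):
        raise ValueError("dispersion model does not match the filtered gene universe")

    s_ref = np.rint(y[:, ref_idx].sum(axis=1)).astype(np.int64)
    s_trt = np.rint(y[:, trt_idx].sum(axis=1)).astype(np.int64)
    n_ref, n_trt = ref_idx.size, trt_idx.size

    pvals = np.array(
        [
            exact_conditional_pvalue(s_ref[g], s_trt[g], n_ref, n_trt, phi[g])
            for g in range(cm.n_genes)
        ]
    )
    mean_ref = y[:, ref_idx].mean(axis=1)
    mean_trt = y[:, trt_idx].mean(axis=1)
    log2fc = log2fc_from_means(mean_ref, mean_trt)
    return build_result("nb_exact", cm.gene_ids, log2fc, pvals, bh_adjust(pvals))
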