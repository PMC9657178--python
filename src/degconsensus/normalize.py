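"""Library-size and composition normalization shared by the DE engines.

Two scale-factor schemes are provided: trimmed mean of M-values (TMM), the
composition-robust scheme of the exact-test family, and median-of-ratios
(MOR) size factors, the scheme of the Wald-test family. Both are computed
from the raw integer counts; engines decide which one they consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tables_io import CountMatrix, ValidationError

__all__ = [
    "NormFactors",
    "library_sizes",
    "cpm",
    "tmm_factors",
    "size_factors_mor",
]

# TMM trim fractions (two-sided) and the family's published defaults.
TMM_M_TRIM = 0.30
TMM_A_TRIM = 0.05


@dataclass(frozen=True)
class NormFactors:
    """Per-sample library sizes and scale factors.

    ``method_tag`` is one of ``tmm``, ``mor``, ``none``. For TMM the scale
    factors have geometric mean 1 and multiply the library size to give an
    effective library size; for MOR the factor itself is the size factor
    (it absorbs sequencing depth).
    """

    sample_names: tuple[str, ...]
    library_sizes: np.ndarray
    scale_factors: np.ndarray
    method_tag: str

    def __post_init__(self) -> None:
        lib = np.asarray(self.library_sizes, dtype=float)
        fac = np.asarray(self.scale_factors, dtype=float)
        if lib.shape != (len(self.sample_names),) or fac.shape != lib.shape:
            raise ValidationError("factor arrays must align with sample names")
        if (lib <= 0).any() or (fac <= 0).any():
            raise ValidationError("library sizes and scale factors must be positive")
        object.__setattr__(self, "library_sizes", lib)
        object.__setattr__(self, "scale_factors", fac)

    @property
    def effective_sizes(self) -> np.ndarray:
        if self.method_tag == "mor":
            return self.scale_factors
        return self.library_sizes * self.scale_factors


def library_sizes(counts: CountMatrix) -> np.ndarray:
    """Per-sample column totals; a zero total is an error."""
    totals = counts.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = counts.sample_names[int(np.argmin(totals))]
        raise ValidationError(f"sample {bad!r} has zero total counts")
    return totals


def cpm(
    counts: CountMatrix, factors: NormFactors | None = None, prior: float = 0.0
) -> np.ndarray:
    """Counts per million effective library size.

    ``value = (count + prior) / (library_size * scale_factor) * 1e6``. With
    ``factors=None`` plain library sizes are used (all scale factors 1).
    """
    if factors is None:
        eff = library_sizes(counts)
    else:
        if factors.sample_names != counts.sample_names:
            raise ValidationError("normalization factors do not match count samples")
        eff = factors.library_sizes * factors.scale_factors
    return (counts.counts + prior) / eff * 1e6


def tmm_factors(counts: CountMatrix) -> NormFactors:
    """Trimmed-mean-of-M scale factors against a reference sample.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile (ties to the first sample). For every other sample,
    genes positive in both are doubly trimmed — the most extreme 30% of
    M-values (log ratios) and 5% of A-values (log abundances) on each side —
    and the factor is 2 to the precision-weighted mean of the surviving
    M-values. Factors are rescaled to geometric mean 1.
    """
    lib = library_sizes(counts)
    x = counts.counts.astype(float)
    cpms = x / lib * 1e6
    uq = np.quantile(cpms, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(x[:, j], lib[j], x[:, ref], lib[ref],
                                   counts.sample_names[j])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        sample_names=counts.sample_names,
        library_sizes=lib,
        scale_factors=factors,
        method_tag="tmm",
    )


def _tmm_pair(
    obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float, name: str
) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn(
            f"sample {name!r} shares no positive gene with the TMM reference; "
            "factor set to 1",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # precision weights: asymptotic variance of M by the delta method
    w = 1.0 / (
        (n_obs - obs[keep]) / (n_obs * obs[keep])
        + (n_ref - ref[keep]) / (n_ref * ref[keep])
    )
    n = m.size
    m_rank = _rank(m)
    a_rank = _rank(a)
    lo_m, hi_m = np.floor(n * TMM_M_TRIM) + 1, n + 1 - (np.floor(n * TMM_M_TRIM) + 1)
    lo_a, hi_a = np.floor(n * TMM_A_TRIM) + 1, n + 1 - (np.floor(n * TMM_A_TRIM) + 1)
    keep2 = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 0.0
    return float(np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))


def _rank(v: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching the trim convention on ties."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    ranks[order] = np.arange(1, v.size + 1)
    # average ties
    uniq, inv = np.unique(v, return_inverse=True)
    sums = np.bincount(inv, weights=ranks)
    cnts = np.bincount(inv)
    return sums[inv] / cnts[inv]


def size_factors_mor(counts: CountMatrix) -> NormFactors:
    """Median-of-ratios size factors.

    For genes positive in every sample, factor_j = median over genes of
    count_gj / geometric-mean_g(count). The factor absorbs sequencing depth.
    """
    x = counts.counts.astype(float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has positive counts in every sample; filter low-count "
            "genes or check the input"
        )
    sub = x[all_pos]
    log_gm = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_gm)[:, None]
    factors = np.median(ratios, axis=0)
    return NormFactors(
        sample_names=counts.sample_names,
        library_sizes=library_sizes(counts),
        scale_factors=factors,
        method_tag="mor",
    )
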