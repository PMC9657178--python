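"""Moment-based NB dispersion estimation with deterministic shrinkage.

The NB variance model is Var = mu + phi * mu^2. Per-gene raw estimates come
from pooled within-condition moments of normalized counts:

    phi_g = max(0, (s2_pooled - mean) / mean^2)

Raw moment estimates are noisy at typical replicate numbers, so both NB
engines use a shrunken value phi~_g = w * target + (1 - w) * phi_g with
w = 0.7. The shrinkage target is the median over filtered genes (``common``
mode, exact-test engine) or a fitted mean-dispersion trend a/mu + b
(``trend`` mode, Wald engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DispersionModel", "estimate_dispersion"]

DEFAULT_SHRINK_WEIGHT = 0.7


@dataclass(frozen=True)
class DispersionModel:
    """Per-gene raw, common/trend and shrunken dispersions."""

    phi_raw: np.ndarray
    common: float
    target: np.ndarray  # per-gene shrink target (common value or trend fit)
    phi_shrunk: np.ndarray
    weight: float
    mode: str  # "common" or "trend"

    def __post_init__(self) -> None:
        if (np.asarray(self.phi_shrunk) < 0).any():
            raise ValueError("shrunken dispersions must be non-negative")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("shrink weight must lie in [0, 1]")


def estimate_dispersion(
    norm_counts: np.ndarray,
    ref_idx: np.ndarray,
    trt_idx: np.ndarray,
    mode: str = "common",
    weight: float = DEFAULT_SHRINK_WEIGHT,
) -> DispersionModel:
    """Estimate per-gene dispersions from normalized counts.

    ``norm_counts`` is genes x samples on a common scale (library-size or
    size-factor normalized); moments are pooled within condition so true DE
    does not inflate the estimate.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    mu = norm_counts.mean(axis=1)
    s2 = _pooled_variance(norm_counts, ref_idx, trt_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
    phi_raw = np.maximum(phi_raw, 0.0)

    positive = phi_raw[phi_raw > 0]
    common = float(np.median(positive)) if positive.size else 0.0

    if mode == "common":
        target = np.full(mu.shape, common)
    elif mode == "trend":
        target = _fit_trend(mu, phi_raw, common)
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")

    phi_shrunk = weight * target + (1.0 - weight) * phi_raw
    return DispersionModel(
        phi_raw=phi_raw,
        common=common,
        target=target,
        phi_shrunk=np.maximum(phi_shrunk, 0.0),
        weight=weight,
        mode=mode,
    )


def _pooled_variance(x: np.ndarray, ref_idx: np.ndarray, trt_idx: np.ndarray) -> np.ndarray:
    """Within-condition pooled sample variance per gene."""
    parts = []
    dof = 0
    for idx in (ref_idx, trt_idx):
        if idx.size >= 2:
            sub = x[:, idx]
            parts.append(np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1))
            dof += idx.size - 1
    if dof == 0:
        # no replication anywhere: fall back to the cross-sample variance
        return x.var(axis=1, ddof=0)
    return sum(parts) / dof


def _fit_trend(mu: np.ndarray, phi_raw: np.ndarray, common: float) -> np.ndarray:
    """Fit phi ~ a/mu + b by least squares in log space; a, b >= 0.

    Only genes with a positive raw estimate inform the fit. Falls back to the
    common value when too few genes are usable or the fit degenerates.
    """
    use = (phi_raw > 0) & (mu > 0)
    if use.sum() < 10:
        return np.full(mu.shape, common)
    mu_u, phi_u = mu[use], phi_raw[use]

    def resid(params):
        a, b = params
        return np.log(a / mu_u + b + 1e-12) - np.log(phi_u)

    try:
        fit = least_squares(
            resid, x0=[common * np.median(mu_u), max(common, 1e-6)],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
        )
        a, b = fit.x
    except Exception:
        return np.full(mu.shape, common)
    trend = np.where(mu > 0, a / np.maximum(mu, 1e-300) + b, common)
    if not np.isfinite(trend).all():
        return np.full(mu.shape, common)
    return trend
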