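"""Empirical-Bayes beta-negative-binomial DE engine (the EB family).

Model: count x_gi ~ NB(size r_g * s_i, success prob q), where s_i is the
median-of-ratios size factor. Under the equal-expression hypothesis (EE) a
single q is drawn from Beta(alpha, beta) and shared by all samples; under
the DE hypothesis each condition draws its own q. Integrating q out gives
closed-form marginal likelihoods through Beta functions; a two-component
mixture with weight pi on DE is fitted by EM, and the per-gene posterior
probability of DE (PPDE) is reported. The unified score column is 1 - PPDE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

from ..normalize import size_factors_mor
from ..tables_io import Dataset
from ._common import DEResult, build_result, expression_filter, filtered_matrix, log2fc_from_means

__all__ = ["eb_test", "EBHyperparams", "marginal_loglik"]

_R_POISSON_CAP = 1e6  # size cap for genes whose moments look Poisson


@dataclass(frozen=True)
class EBHyperparams:
    """Beta prior (alpha, beta), per-gene sizes r_g, and the DE weight pi."""

    alpha: float
    beta: float
    r: np.ndarray
    pi_de: float


def marginal_loglik(
    counts: np.ndarray, sizes: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """log of the Beta-NB marginal for samples sharing one q, per gene.

    ``counts``: genes x samples (integers); ``sizes``: genes x samples NB
    size parameters r_gi. The per-sample binomial-coefficient terms are
    included so likelihoods are comparable across hypotheses.
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    comb = gammaln(counts + sizes) - gammaln(sizes) - gammaln(counts + 1.0)
    return (
        comb.sum(axis=1)
        + betaln(alpha + sizes.sum(axis=1), beta + counts.sum(axis=1))
        - betaln(alpha, beta)
    )


def _estimate_hyperparams(
    counts: np.ndarray, sf: np.ndarray, ref_idx: np.ndarray, trt_idx: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Method-of-moments r_g and pooled Beta(alpha, beta).

    The variance entering r_g = m^2 / (v - m) is pooled within condition so
    a true expression difference does not masquerade as overdispersion.
    """
    norm = counts / sf
    m = norm.mean(axis=1)
    v = _pooled_var(norm, ref_idx, trt_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(v > m, m**2 / (v - m), _R_POISSON_CAP)
    r = np.clip(r, 1e-3, _R_POISSON_CAP)
    q_hat = np.clip(r / (r + m), 1e-6, 1.0 - 1e-6)
    mu_q = q_hat.mean()
    var_q = q_hat.var(ddof=1)
    var_q = min(var_q, mu_q * (1 - mu_q) * 0.999) if var_q > 0 else mu_q * (1 - mu_q) * 1e-3
    conc = mu_q * (1 - mu_q) / var_q - 1.0
    conc = max(conc, 1e-2)
    return float(mu_q * conc), float((1 - mu_q) * conc), r


def _pooled_var(x: np.ndarray, ref_idx: np.ndarray, trt_idx: np.ndarray) -> np.ndarray:
    parts = []
    dof = 0
    for idx in (ref_idx, trt_idx):
        if idx.size >= 2:
            sub = x[:, idx]
            parts.append(np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1))
            dof += idx.size - 1
    if dof == 0:
        return x.var(axis=1, ddof=0)
    return sum(parts) / dof


def eb_test(
    ds: Dataset,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
    pi_de: float | None = None,
    hyper: EBHyperparams | None = None,
) -> DEResult:
    """Posterior probability of DE per gene via the beta-NB mixture.

    EM starts from pi = 0.5 and updates the mixture weight until the change
    falls below ``em_tol`` or ``em_max_iter`` iterations. ``pi_de`` pins the
    weight (no EM); ``hyper`` pins all hyperparameters.
    """
    keep = expression_filter(ds)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    cm = filtered_matrix(ds, keep)
    ref_idx, trt_idx = ds.group_indices()

    sf = size_factors_mor(cm).scale_factors
    x = cm.counts.astype(float)

    if hyper is None:
        alpha, beta, r = _estimate_hyperparams(x, sf, ref_idx, trt_idx)
    else:
        alpha, beta, r = hyper.alpha, hyper.beta, np.asarray(hyper.r, dtype=float)
        if r.shape != (cm.n_genes,):
            raise ValueError("hyperparameter r does not match the gene universe")
    sizes = r[:, None] * sf[None, :]

    ll_ee = marginal_loglik(x, sizes, alpha, beta)
    ll_de = marginal_loglik(x[:, ref_idx], sizes[:, ref_idx], alpha, beta) + marginal_loglik(
        x[:, trt_idx], sizes[:, trt_idx], alpha, beta
    )

    if pi_de is not None:
        pi = float(pi_de)
    elif hyper is not None and hyper.pi_de is not None:
        pi = float(hyper.pi_de)
    else:
        pi = _em_pi(ll_ee, ll_de, em_max_iter, em_tol)

    ppde = _posterior(ll_ee, ll_de, pi)
    score = 1.0 - ppde

    norm = x / sf
    log2fc = log2fc_from_means(norm[:, ref_idx].mean(axis=1), norm[:, trt_idx].mean(axis=1))
    return build_result("eb", cm.gene_ids, log2fc, score, score)


def _posterior(ll_ee: np.ndarray, ll_de: np.ndarray, pi: float) -> np.ndarray:
    if pi <= 0.0:
        return np.zeros_like(ll_ee)
    if pi >= 1.0:
        return np.ones_like(ll_ee)
    delta = ll_de - ll_ee
    return 1.0 / (1.0 + np.exp(np.clip(np.log1p(-pi) - np.log(pi) - delta, -700, 700)))


def _em_pi(ll_ee: np.ndarray, ll_de: np.ndarray, max_iter: int, tol: float) -> float:
    pi = 0.5
    for _ in range(max_iter):
        ppde = _posterior(ll_ee, ll_de, pi)
        new_pi = float(np.clip(ppde.mean(), 0.0, 1.0))
        if abs(new_pi - pi) < tol:
            return new_pi
        pi = new_pi
    warnings.warn(
        f"EM for the DE mixture weight did not converge in {max_iter} iterations; "
        "using the last iterate",
        UserWarning,
        stacklevel=3,
    )
    return pi
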