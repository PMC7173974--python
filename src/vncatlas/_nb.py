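"""Negative-binomial likelihood machinery for the one-vs-rest marker test.

Model for one gene: count y_i ~ NB(mean mu_i, dispersion a) with
mu_i = N_i * r_{g_i}, where N_i is the cell's total UMI (a log offset) and
r_g a per-group rate.  The dispersion is shared across groups within one
gene's test and profiled out by maximum likelihood.  The test statistic is
the likelihood ratio between the two-rate (cluster vs rest) and one-rate
models, referred to chi-square with 1 df.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = ["nb_loglik", "fit_rate", "profile_loglik", "nb_lrt", "mom_dispersion"]

_LOG_ALPHA_BOUNDS = (-12.0, 5.0)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Sum of NB log-pmf with mean mu and variance mu + alpha*mu^2."""
    if alpha < 1e-12:
        # Poisson limit
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
        return float(np.sum(t - mu - gammaln(y + 1)))
    k = 1.0 / alpha
    amu = alpha * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(
            y > 0,
            y * np.log(np.maximum(amu, 1e-300) / (1.0 + amu)),
            0.0,
        )
    return float(
        np.sum(
            gammaln(y + k) - gammaln(k) - gammaln(y + 1) + term - k * np.log1p(amu)
        )
    )


def fit_rate(y: np.ndarray, N: np.ndarray, alpha: float) -> float:
    """MLE of the rate r for fixed dispersion: solves
    sum (y - N r) / (1 + a N r) = 0 by Newton with bisection safeguards."""
    sy = y.sum()
    if sy == 0:
        return 0.0
    r = sy / N.sum()
    if alpha < 1e-12:
        return float(r)
    for _ in range(50):
        denom = 1.0 + alpha * N * r
        s = np.sum((y - N * r) / denom)
        ds = -np.sum(N * (1.0 + alpha * y) / denom**2)
        step = s / ds
        r_new = r - step
        if r_new <= 0:
            r_new = r / 2.0
        if abs(r_new - r) <= 1e-12 * max(r, 1e-300):
            r = r_new
            break
        r = r_new
    return float(r)


def profile_loglik(y: np.ndarray, N: np.ndarray, groups: np.ndarray, alpha: float) -> float:
    """Log-likelihood at the rate MLEs for fixed dispersion; ``groups`` is an
    integer label per observation (a single group fits the null model)."""
    ll = 0.0
    mu = np.empty_like(N, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        r = fit_rate(y[m], N[m], alpha)
        mu[m] = N[m] * r
    ll = nb_loglik(y, np.maximum(mu, 1e-300), alpha)
    return ll


def mom_dispersion(y: np.ndarray, N: np.ndarray) -> float:
    """Method-of-moments dispersion on offset-standardised counts."""
    r = y.sum() / N.sum() if N.sum() > 0 else 0.0
    mu = N * r
    good = mu > 0
    if good.sum() < 2:
        return 1e-8
    z = (y[good] - mu[good]) ** 2 - mu[good]
    denom = np.sum(mu[good] ** 2)
    return float(max(np.sum(z) / denom, 1e-8)) if denom > 0 else 1e-8


def _max_profile(y, N, groups) -> tuple[float, float, bool]:
    """Maximise the profile likelihood over dispersion.

    Returns (loglik, alpha_hat, fallback) where ``fallback`` marks a
    non-converged optimisation resolved with the method-of-moments value."""
    res = minimize_scalar(
        lambda la: -profile_loglik(y, N, groups, np.exp(la)),
        bounds=_LOG_ALPHA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-4},
    )
    if res.success and np.isfinite(res.fun):
        return -float(res.fun), float(np.exp(res.x)), False
    a = mom_dispersion(y, N)
    return profile_loglik(y, N, groups, a), a, True


def nb_lrt(y: np.ndarray, N: np.ndarray, in_cluster: np.ndarray):
    """One-vs-rest NB likelihood-ratio test for one gene.

    Returns ``(p_value, alpha_hat, fallback_flag)``.
    """
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    groups = in_cluster.astype(int)
    ll_alt, alpha_hat, fb1 = _max_profile(y, N, groups)
    ll_null, _, fb2 = _max_profile(y, N, np.zeros_like(groups))
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(chi2.sf(stat, df=1)), alpha_hat, (fb1 or fb2)
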