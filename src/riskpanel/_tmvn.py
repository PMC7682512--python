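"""Rectangle probabilities and moments of box-truncated multivariate normals.

``mvn_rectangle`` wraps scipy's Genz-type quasi-Monte-Carlo integrator with a
pinned integration stream so repeated calls agree to the requested accuracy.
``truncated_mvn_moments`` implements the Tallis moment formulas in the
doubly-truncated generalisation of Manjunath & Wilhelm: first and second
moments of X ~ N(0, S) conditional on a <= X <= b, where each bound may be
infinite.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = ["mvn_rectangle", "truncated_mvn_moments"]

_INTEGRATOR_SEED = 20200629  # pinned: rectangle probabilities are reproducible


def mvn_rectangle(lower, upper, cov, mean=None, abseps=1e-6, maxpts=None) -> float:
    """P(lower <= X <= upper) for X ~ N(mean, cov), bounds may be infinite."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    m = cov.shape[0]
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (m,)).copy()
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (m,)).copy()
    if mean is not None:
        mean = np.broadcast_to(np.asarray(mean, dtype=float), (m,))
        lower = lower - mean
        upper = upper - mean
    if np.any(upper <= lower):
        return 0.0
    # coordinates unconstrained on both sides integrate out exactly
    keep = ~(np.isinf(lower) & (lower < 0) & np.isinf(upper) & (upper > 0))
    if not keep.all():
        if not keep.any():
            return 1.0
        lower, upper = lower[keep], upper[keep]
        cov = cov[np.ix_(keep, keep)]
        m = cov.shape[0]
    sd = np.sqrt(np.diag(cov))
    # clip infinities: 15 sd is far beyond double-precision tail mass
    lim = 15.0 * np.where(sd > 0, sd, 1.0)
    lower = np.maximum(lower, -lim)
    upper = np.minimum(upper, lim)
    if m == 1:
        s = sd[0] if sd[0] > 0 else 1e-300
        return float(norm.cdf(upper[0] / s) - norm.cdf(lower[0] / s))
    if maxpts is None:
        maxpts = 1_000_000 * m
    val = multivariate_normal.cdf(
        upper,
        mean=np.zeros(m),
        cov=cov,
        lower_limit=lower,
        abseps=abseps,
        releps=0.0,
        maxpts=maxpts,
        rng=np.random.default_rng(_INTEGRATOR_SEED),
        allow_singular=True,
    )
    return float(min(max(val, 0.0), 1.0))


def _cond_rectangle(cov, lower, upper, fixed_idx, fixed_val, abseps) -> float:
    """Rectangle probability of the remaining coordinates given X[fixed] = val."""
    m = cov.shape[0]
    rest = [i for i in range(m) if i not in fixed_idx]
    if not rest:
        return 1.0
    F = np.asarray(fixed_idx)
    R = np.asarray(rest)
    Sff = cov[np.ix_(F, F)]
    Srf = cov[np.ix_(R, F)]
    sol = np.linalg.solve(Sff, np.asarray(fixed_val, dtype=float))
    mu = Srf @ sol
    Sc = cov[np.ix_(R, R)] - Srf @ np.linalg.solve(Sff, Srf.T)
    return mvn_rectangle(lower[R], upper[R], Sc, mean=mu, abseps=abseps)


def truncated_mvn_moments(cov, lower, upper, abseps=1e-7):
    """Mean, covariance and probability of N(0, cov) truncated to [lower, upper].

    Returns ``(mean, cov_trunc, prob)``.  Raises ``ValueError`` when the
    rectangle probability falls below 1e-12 (an effectively empty cell).
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    m = cov.shape[0]
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (m,)).astype(float)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (m,)).astype(float)
    alpha = mvn_rectangle(lower, upper, cov, abseps=abseps)
    if alpha < 1e-12:
        raise ValueError(f"truncation region has probability {alpha:.3g} < 1e-12")
    sd = np.sqrt(np.diag(cov))

    def F1(k, x):
        # marginal density of X_k at x times the conditional rectangle mass
        if not np.isfinite(x):
            return 0.0
        dens = norm.pdf(x / sd[k]) / sd[k]
        if dens == 0.0:
            return 0.0
        return dens * _cond_rectangle(cov, lower, upper, [k], [x], abseps)

    def F2(k, q, x, y):
        if not (np.isfinite(x) and np.isfinite(y)):
            return 0.0
        S2 = cov[np.ix_([k, q], [k, q])]
        det = np.linalg.det(S2)
        if det <= 0:
            return 0.0
        v = np.array([x, y])
        dens = np.exp(-0.5 * v @ np.linalg.solve(S2, v)) / (2 * np.pi * np.sqrt(det))
        if dens == 0.0:
            return 0.0
        return dens * _cond_rectangle(cov, lower, upper, [k, q], [x, y], abseps)

    Fa = np.array([F1(k, lower[k]) for k in range(m)])
    Fb = np.array([F1(k, upper[k]) for k in range(m)])
    mean = cov @ (Fa - Fb) / alpha

    # second raw moments
    second = np.array(cov, dtype=float, copy=True)
    aFa = np.where(np.isfinite(lower), lower, 0.0) * Fa
    bFb = np.where(np.isfinite(upper), upper, 0.0) * Fb
    F2_cache = {}

    def F2c(k, q, x, y):
        key = (k, q, float(x), float(y))
        if key not in F2_cache:
            F2_cache[key] = F2(k, q, x, y)
        return F2_cache[key]

    add = np.zeros((m, m))
    for k in range(m):
        skk = cov[k, k]
        for j in range(m):
            term = cov[j, k] / skk * (aFa[k] - bFb[k])
            for q in range(m):
                if q == k:
                    continue
                coef = cov[j, q] - cov[k, q] * cov[j, k] / skk
                if coef == 0.0:
                    continue
                rect = (
                    F2c(k, q, lower[k], lower[q])
                    - F2c(k, q, lower[k], upper[q])
                    - F2c(k, q, upper[k], lower[q])
                    + F2c(k, q, upper[k], upper[q])
                )
                term += coef * rect
            add[:, j] += cov[:, k] * term / alpha
    second = second + (add + add.T) / 2.0
    cov_trunc = second - np.outer(mean, mean)
    cov_trunc = (cov_trunc + cov_trunc.T) / 2.0
    return mean, cov_trunc, alpha
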