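"""Quantitative-trait simulation and single-component REML heritability.

The model is the standard linear mixed model for a relatedness matrix K
(here K = 2*Phi, twice the kinship matrix, so diag(K) = 1 for outbred
individuals):

    y ~ N(X beta, sigma_g^2 K + sigma_e^2 I),   h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Traits are simulated from N(0, h^2 K + (1 - h^2) I); at h^2 = 0.5 this is
(2 Phi + I)/2, i.e. the y ~ N(0, 2 Phi + I) family up to an overall scale
that REML heritability is invariant to.

REML works in the eigenbasis of K: with K = U L U', the covariance is
diagonal after rotating y and X by U', and the restricted likelihood reduces
to a one-dimensional profile over h^2 in [0, 1] (the total variance and the
fixed effects are profiled out in closed form). The profile is maximized by
bounded scalar optimization; the standard error comes from the curvature of
the restricted log-likelihood at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = ["RemlResult", "floor_psd", "simulate_traits", "reml_h2"]

PSD_FLOOR = 1e-6


@dataclass
class RemlResult:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    boundary: bool


def floor_psd(K: np.ndarray, floor: float = PSD_FLOOR) -> np.ndarray:
    """Repair an indefinite relatedness matrix by flooring its eigenvalues.

    Moment estimates of kinship from finite SNP sets can be indefinite;
    clipping eigenvalues at a small positive floor restores a usable
    covariance while perturbing the matrix minimally.
    """
    K = np.asarray(K, dtype=float)
    K = 0.5 * (K + K.T)
    vals, vecs = np.linalg.eigh(K)
    if vals.min() >= floor:
        return K
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def simulate_traits(
    relatedness: np.ndarray, h2: float, n_reps: int, seed=None
) -> np.ndarray:
    """Draw n_reps trait vectors from N(0, h2*K + (1-h2)*I); returns (n, n_reps)."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    K = np.asarray(relatedness, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("relatedness must be square")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = K.shape[0]
    cov = h2 * floor_psd(K) + (1.0 - h2) * np.eye(n)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal((n, n_reps))


def _neg_restricted_loglik(h2, lam, yt, xt):
    """-2x restricted log-likelihood (up to constants), profiled over the
    total variance and the fixed effects, in the eigenbasis of K."""
    d = h2 * lam + (1.0 - h2)
    if d.min() <= 0:
        return np.inf
    w = 1.0 / d
    xtx = xt.T @ (xt * w[:, None])
    xty = xt.T @ (yt * w)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yt - xt @ beta
    n, q = xt.shape
    rss = float(resid @ (resid * w))
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0 or rss <= 0:
        return np.inf
    return (n - q) * np.log(rss) + np.log(d).sum() + logdet_xtx


def reml_h2(
    y: np.ndarray,
    relatedness: np.ndarray,
    X: np.ndarray | None = None,
    eig: tuple | None = None,
) -> RemlResult:
    """Estimate h^2 by restricted maximum likelihood.

    Parameters
    ----------
    y : (n,) trait vector.
    relatedness : (n, n) matrix K = 2*Phi (floored to PSD internally).
    X : optional (n, q) fixed-effect design; an intercept column is added if
        no constant column is present.
    eig : optional precomputed ``(eigenvalues, eigenvectors)`` of the floored
        relatedness matrix, to amortize the decomposition across replicates.

    Returns the estimate, a curvature-based standard error, the implied
    variance components on the observed scale, and a boundary flag (set when
    the optimum pins to 0 or 1, or when K carries no relatedness signal).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if not np.any(np.all(X == X[0], axis=0) & (X[0] != 0)):
            X = np.column_stack([np.ones(n), X])
    if n <= X.shape[1] + 1:
        raise ValueError("need n > q + 1 observations")
    if eig is None:
        lam, U = np.linalg.eigh(floor_psd(relatedness))
    else:
        lam, U = eig
    if np.ptp(lam) < 1e-10:
        logger.warning("relatedness matrix is (a multiple of) identity; h2 unidentifiable")
        return RemlResult(0.0, np.nan, 0.0, float(np.var(y)), np.nan, True)
    yt = U.T @ y
    xt = U.T @ X

    obj = lambda h2: _neg_restricted_loglik(h2, lam, yt, xt)
    res = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-7})
    h2 = float(res.x)
    # bounded Brent never returns the exact endpoints; snap if flat there
    for edge in (0.0, 1.0):
        if obj(edge) <= res.fun:
            h2, res = edge, res
            break
    boundary = h2 <= 1e-6 or h2 >= 1.0 - 1e-6

    # observed-scale variance components at the optimum
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    xtx = xt.T @ (xt * w[:, None])
    beta = np.linalg.solve(xtx, xt.T @ (yt * w))
    resid = yt - xt @ beta
    q = xt.shape[1]
    sigma_tot = float(resid @ (resid * w)) / (n - q)
    sigma_g2 = h2 * sigma_tot
    sigma_e2 = (1.0 - h2) * sigma_tot

    # SE from the curvature of the restricted log-likelihood (central diff)
    step = 1e-3
    lo, hi = max(h2 - step, 0.0), min(h2 + step, 1.0)
    f0, flo, fhi = obj(h2), obj(lo), obj(hi)
    denom = (hi - h2) * (h2 - lo)
    if denom > 0 and np.isfinite(flo) and np.isfinite(fhi):
        # obj is -2 loglik; information = 0.5 * d2(obj)/dh2^2
        second = (flo + fhi - 2 * f0) / ((0.5 * (hi - lo)) ** 2)
        se = float(np.sqrt(2.0 / second)) if second > 0 else np.nan
    else:
        se = np.nan
    return RemlResult(
        h2=h2,
        se=se,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        loglik=-0.5 * float(f0),
        boundary=boundary,
    )
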