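"""Negative-binomial GLM fitting for per-feature count models.

The model for one feature is k_j ~ NB(mu_j, alpha) with log link
log mu_j = x_j' beta + log s_j, variance mu + alpha * mu^2.  beta is
estimated by iteratively reweighted least squares at fixed dispersion;
the dispersion alpha is a per-feature Cox-Reid adjusted profile-likelihood
MLE (beta re-maximized at each alpha), method-of-moments initialized,
floored at 1e-8 and capped at 10.  No shrinkage of dispersions across
features is applied.  Everything here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 10.0
MAX_ITER = 100
TOL = 1e-8


@dataclass
class NBFit:
    """One converged (or flagged) NB GLM fit."""

    beta: np.ndarray
    alpha: float
    mu: np.ndarray
    loglik: float
    cov: Optional[np.ndarray]  # inverse expected Fisher information
    converged: bool


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; smoothly degenerates to Poisson as alpha -> 0."""
    mu = np.maximum(mu, 1e-300)
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    beta0: Optional[np.ndarray] = None,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple:
    """IRLS for beta at fixed alpha. Returns (beta, mu, converged, XtWX)."""
    n, p = X.shape
    if beta0 is None:
        # working init from log of mildly regularized counts
        z0 = np.log(y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    converged = False
    XtWX = None
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -500, 500)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        XtWX = XtW @ X
        try:
            beta_new = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtWX, XtW @ z, rcond=None)[0]
        step = beta_new - beta
        beta = beta_new
        ll = nb_loglik(y, np.exp(np.clip(X @ beta + offset, -500, 500)), alpha)
        if np.max(np.abs(step)) < tol or abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    eta = np.clip(X @ beta + offset, -500, 500)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    XtWX = (X.T * W) @ X
    return beta, mu, converged, XtWX


def mom_dispersion(y: np.ndarray, sf: np.ndarray) -> float:
    """Method-of-moments dispersion on size-factor-normalized counts."""
    q = y / sf
    m = q.mean()
    if m <= 0:
        return ALPHA_FLOOR
    v = q.var(ddof=1)
    alpha = (v - m) / (m * m)
    return float(np.clip(alpha, ALPHA_FLOOR, ALPHA_CAP))


def fit_nbglm(
    y: np.ndarray,
    sf: np.ndarray,
    X: np.ndarray,
    alpha: Optional[float] = None,
    profile_maxiter: int = 30,
) -> NBFit:
    """Fit the NB GLM for one feature.

    When ``alpha`` is None the dispersion is profiled: for each candidate
    alpha (searched on the log scale within [1e-8, 10]) beta is re-fitted
    and the NB log-likelihood evaluated at the maximizing beta; the alpha
    with the highest profile likelihood is kept and beta/covariance
    re-fitted at full tolerance there.
    """
    y = np.asarray(y, dtype=float)
    sf = np.asarray(sf, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design matrix rows must match sample count")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    offset = np.log(sf)

    if alpha is None:
        alpha0 = mom_dispersion(y, sf)

        def neg_profile(log_a: float) -> float:
            # Cox-Reid adjusted profile likelihood: the 0.5*logdet term
            # compensates for the coefficients estimated alongside the
            # dispersion, removing the downward bias of the plain MLE
            a = float(np.exp(log_a))
            beta, mu, _, XtWX = _irls(y, X, offset, a, tol=1e-6, max_iter=50)
            sign, logdet = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return np.inf
            return -(nb_loglik(y, mu, a) - 0.5 * logdet)

        lo, hi = np.log(ALPHA_FLOOR), np.log(ALPHA_CAP)
        res = minimize_scalar(
            neg_profile,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-3, "maxiter": profile_maxiter},
        )
        # bounded search can miss a boundary optimum; compare explicitly
        candidates = [float(res.x), float(np.log(np.clip(alpha0, ALPHA_FLOOR, ALPHA_CAP))), lo]
        best = min(candidates, key=neg_profile)
        alpha = float(np.exp(best))

    beta, mu, converged, XtWX = _irls(y, X, offset, alpha)
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = None
    return NBFit(
        beta=beta,
        alpha=float(alpha),
        mu=mu,
        loglik=nb_loglik(y, mu, alpha),
        cov=cov,
        converged=converged,
    )
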