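"""Fast profiled-REML linear mixed model with per-group random
intercept (+ optional slope).

The association scans and the cluster bootstrap refit the same small mixed
model thousands of times (per tract x metric, per replicate), which makes
a general-purpose LMM implementation the bottleneck.  This solver exploits
the model's structure: with V_i = sigma^2 (I + Z_i G Z_i') per group, the
fixed effects and sigma^2 are profiled out in closed form (Woodbury
identity on the q x q core, batched over groups), leaving a q(q+1)/2
dimensional optimization over the log-Cholesky factor of G = Psi / sigma^2.
For q = 2 that is a 3-parameter Nelder-Mead over criterion evaluations
costing O(groups) batched 2x2 algebra each.

Estimates agree with ``statsmodels.MixedLM`` (which serves as the
independent cross-check in the test suite) to optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["LMMResult", "fit_lmm", "theta_from_psi"]


def theta_from_psi(psi: np.ndarray, sigma2: float) -> np.ndarray:
    """Log-Cholesky warm-start parameters from a fitted (Psi, sigma^2)."""
    q = psi.shape[0]
    G = psi / max(sigma2, 1e-300) + 1e-10 * np.eye(q)
    L = np.linalg.cholesky(G)
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
    return np.asarray(out)


@dataclass
class LMMResult:
    """Fitted mixed model: GLS fixed effects and variance components."""

    beta: np.ndarray          # fixed effects
    cov_beta: np.ndarray      # GLS covariance of beta
    psi: np.ndarray           # random-effect covariance (q x q)
    sigma2: float             # residual variance
    converged: bool
    reml_criterion: float
    n_obs: int
    n_groups: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _suffstats(y, X, Z, groups):
    """Per-group sufficient statistics, batched into dense arrays."""
    order = np.argsort(groups, kind="stable")
    y, X, Z, groups = y[order], X[order], Z[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    bounds = np.append(starts, len(y))
    m = len(starts)
    p, q = X.shape[1], Z.shape[1]
    ZtZ = np.empty((m, q, q))
    ZtX = np.empty((m, q, p))
    Zty = np.empty((m, q))
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    for k in range(m):
        s, e = bounds[k], bounds[k + 1]
        Zi, Xi, yi = Z[s:e], X[s:e], y[s:e]
        ZtZ[k] = Zi.T @ Zi
        ZtX[k] = Zi.T @ Xi
        Zty[k] = Zi.T @ yi
        XtX += Xi.T @ Xi
        Xty += Xi.T @ yi
        yty += yi @ yi
    return ZtZ, ZtX, Zty, XtX, Xty, yty, m


def _unpack_chol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(np.clip(theta[idx], -15.0, 15.0))
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


def fit_lmm(y, X, groups, Z=None, reml: bool = True,
            theta0: np.ndarray | None = None) -> LMMResult:
    """Fit y = X beta + Z_i b_i + eps with b_i ~ N(0, Psi), batched REML.

    Parameters
    ----------
    Z
        Within-group random-effects design (n x q); default a column of
        ones (random intercept only).
    theta0
        Optional warm start for the log-Cholesky parameters of Psi/sigma^2
        (e.g. from a fit on the un-resampled data).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if Z is None:
        Z = np.ones((len(y), 1))
    Z = np.asarray(Z, float)
    groups = np.asarray(groups)
    n, p = X.shape
    q = Z.shape[1]
    ZtZ, ZtX, Zty, XtX, Xty, yty, m = _suffstats(y, X, Z, groups)
    dof = n - p if reml else n
    eye_q = np.eye(q)

    def core(theta):
        """Criterion pieces for G = L L' (scaled random covariance)."""
        L = _unpack_chol(theta, q)
        # |I + Z G Z'| = |I_q + L' Z'Z L|;  W = I - Z L A^-1 L' Z'
        A = eye_q[None] + L.T @ ZtZ @ L
        if q == 2:      # closed-form batched 2x2 inverse/determinant
            a, b, c, d = A[:, 0, 0], A[:, 0, 1], A[:, 1, 0], A[:, 1, 1]
            det = a * d - b * c
            if np.any(det <= 0):
                return None
            logdetA = np.log(det).sum()
            Ainv = np.empty_like(A)
            Ainv[:, 0, 0], Ainv[:, 1, 1] = d / det, a / det
            Ainv[:, 0, 1], Ainv[:, 1, 0] = -b / det, -c / det
        elif q == 1:
            det = A[:, 0, 0]
            if np.any(det <= 0):
                return None
            logdetA = np.log(det).sum()
            Ainv = 1.0 / A
        else:
            sign, ld = np.linalg.slogdet(A)
            if np.any(sign <= 0):
                return None
            logdetA = ld.sum()
            Ainv = np.linalg.inv(A)
        # U = L' Z'X (k,q,p), v = L' Z'y (k,q)
        U = L.T @ ZtX
        v = Zty @ L
        T = Ainv @ U                             # (k, q, p)
        Av = (Ainv @ v[:, :, None])[:, :, 0]     # (k, q)
        XtWX = XtX - np.tensordot(U, T, axes=([0, 1], [0, 1]))
        XtWy = Xty - np.tensordot(U, Av[:, :, None], axes=([0, 1], [0, 1]))[:, 0]
        ytWy = yty - float(np.sum(v * Av))
        return L, logdetA, XtWX, XtWy, ytWy

    def criterion(theta):
        parts = core(theta)
        if parts is None:
            return 1e12
        _, logdetV, XtWX, XtWy, ytWy = parts
        try:
            c = np.linalg.cholesky(XtWX)
        except np.linalg.LinAlgError:
            return 1e12
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, 1e-300)
        crit = dof * np.log(rss / dof) + logdetV
        if reml:
            crit += 2.0 * np.log(np.diag(c)).sum()
        return float(crit)

    n_theta = q * (q + 1) // 2
    if theta0 is None:
        theta0 = np.full(n_theta, -0.5)
        theta0[[i * (i + 1) // 2 + i for i in range(q)]] = -0.5
    res = minimize(criterion, np.asarray(theta0, float),
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 2000})
    parts = core(res.x)
    if parts is None:
        raise RuntimeError("mixed-model criterion undefined at the optimum")
    L, logdetV, XtWX, XtWy, ytWy = parts
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - beta @ XtWy, 1e-300)
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    psi = sigma2 * (L @ L.T)
    return LMMResult(beta=beta, cov_beta=cov_beta, psi=psi,
                     sigma2=float(sigma2), converged=bool(res.success),
                     reml_criterion=float(res.fun), n_obs=n, n_groups=m)
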