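"""Lean logistic-regression primitives for the permutation engine.

User-facing estimates (odds ratios, Wald intervals, likelihood-ratio tests)
go through :mod:`statsmodels`; the permutation engine, however, refits on the
order of ``B x n_snps`` small logistic models per run, so it uses the
Newton/IRLS fitter and Rao score tests below.  Agreement with statsmodels is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import chdtrc, expit

# |beta| beyond this is treated as drifting to the boundary (separation)
_SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """Result of a Newton/IRLS logistic fit. ``X`` must carry the intercept."""

    beta: np.ndarray
    loglik: float
    cov: np.ndarray | None
    converged: bool
    n_iter: int

    @property
    def separated(self) -> bool:
        return bool(np.abs(self.beta).max() > _SEPARATION_BOUND)

    @property
    def ok(self) -> bool:
        return self.converged and not self.separated and self.cov is not None


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton-Raphson with step halving.

    A tiny ridge on the Hessian keeps near-collinear designs solvable; the
    ``separated`` flag marks runaway coefficients rather than raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll = _loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        H.flat[:: p + 1] += ridge
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        scale = 1.0
        ll_new = ll
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:  # no ascent direction found
            break
        improve = ll_new - ll
        beta, ll = cand, ll_new
        if improve < tol:
            converged = True
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    H.flat[:: p + 1] += ridge
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return LogisticFit(beta=beta, loglik=ll, cov=cov, converged=converged, n_iter=it)


def wald_pvalue(fit: LogisticFit, j: int = -1) -> float:
    """Two-sided Wald p-value for coefficient ``j`` (default: last column)."""
    if fit.cov is None:
        return np.nan
    var = fit.cov[j, j]
    if not np.isfinite(var) or var <= 0:
        return np.nan
    z = fit.beta[j] / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def score_add_pvalues(
    Z: np.ndarray, y: np.ndarray, X: np.ndarray, fit: LogisticFit
) -> np.ndarray:
    """Rao 1-df score test for adding each column of ``X`` to the null ``Z``-fit.

    Vectorised over columns: U_j = x_j'(y - mu),
    V_j = x_j'W x_j - x_j'WZ (Z'WZ)^-1 Z'W x_j, stat = U^2/V ~ chi2(1).
    Columns with non-positive V (collinear with Z) get p = NaN.
    """
    mu = expit(Z @ fit.beta)
    w = mu * (1.0 - mu)
    r = y - mu
    U = X.T @ r
    ZW = Z * w[:, None]
    G = ZW.T @ Z
    A = ZW.T @ X
    try:
        B = np.linalg.solve(G, A)
    except np.linalg.LinAlgError:
        B = np.linalg.lstsq(G, A, rcond=None)[0]
    V = np.einsum("ij,ij->j", X * w[:, None], X) - np.einsum("ij,ij->j", A, B)
    pvals = np.full(X.shape[1], np.nan)
    good = V > 1e-12
    stat = np.zeros_like(V)
    stat[good] = U[good] ** 2 / V[good]
    pvals[good] = chdtrc(1, stat[good])
    return pvals


def score_block_pvalue(
    D: np.ndarray, y: np.ndarray, C: np.ndarray, fit: LogisticFit
) -> float:
    """Rao score test for adding the column block ``C`` to the fitted null ``D``.

    Returns the chi-square tail probability with df = C.shape[1], or NaN when
    the score variance is singular (collinear interaction columns).
    """
    mu = expit(D @ fit.beta)
    w = mu * (1.0 - mu)
    r = y - mu
    U = C.T @ r
    DW = D * w[:, None]
    G = DW.T @ D
    A = DW.T @ C
    try:
        B = np.linalg.solve(G, A)
    except np.linalg.LinAlgError:
        B = np.linalg.lstsq(G, A, rcond=None)[0]
    V = (C * w[:, None]).T @ C - A.T @ B
    try:
        stat = float(U @ np.linalg.solve(V, U))
    except np.linalg.LinAlgError:
        return np.nan
    if not np.isfinite(stat) or stat < 0:
        return np.nan
    return float(chdtrc(C.shape[1], stat))


def firth_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> LogisticFit:
    """Firth bias-reduced logistic fit (Jeffreys-prior penalised likelihood).

    The modified score U* = X'(y - mu + h (1/2 - mu)), with h the hat
    diagonals of W^(1/2) X (X'WX)^-1 X' W^(1/2), removes the O(1/n)
    bias of the MLE and keeps estimates finite under separation — the
    standard estimator for sparse strata.  ``cov`` is (X'WX)^-1 at the
    solution (the usual Wald covariance for Firth fits).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)

    def _penalised(beta):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, mu, w, H
        return _loglik(eta, y) + 0.5 * logdet, mu, w, H

    ll, mu, w, H = _penalised(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, Hinv, X) * w
        grad = X.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ grad
        scale = 1.0
        ll_new, mu_new, w_new, H_new = ll, mu, w, H
        for _ in range(30):
            cand = beta + scale * step
            ll_new, mu_new, w_new, H_new = _penalised(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        improve = ll_new - ll
        beta, ll, mu, w, H = cand, ll_new, mu_new, w_new, H_new
        if improve < tol and np.abs(grad).max() < 1e-5:
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return LogisticFit(beta=beta, loglik=ll, cov=cov, converged=converged, n_iter=it)
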