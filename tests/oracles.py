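"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the Hardy-Weinberg conditional distribution, a literal
double-loop Benjamini-Hochberg step-up, and a nested double-permutation
estimate of the adaptive rank truncated product p-value built on a
closed-form trend (score) test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import chi2


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by full enumeration with exact integer weights."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_alt + n_het, 2 * n_hom_ref + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        # multinomial arrangements x 2^h phase choices for heterozygotes
        weights[h] = comb(n, h) * comb(n - h, n_rr) * 2**h
    total = sum(weights.values())
    w_obs = weights[n_het]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(tail, total))


def bh_stepup_oracle(pvals: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def trend_pvals_rows(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Closed-form 1-df score (trend) test p-values for each status row of Y."""
    n = X.shape[0]
    ybar = Y.mean(axis=1, keepdims=True)
    w = (ybar * (1.0 - ybar)).ravel()
    U = (Y - ybar) @ X
    V = (X**2).sum(axis=0) - X.sum(axis=0) ** 2 / n
    stat = U**2 / np.outer(w, np.maximum(V, 1e-300))
    return np.clip(chi2.sf(stat, 1), 1e-300, 1.0)


def _minp_observed(y_row: np.ndarray, X: np.ndarray, ks, B_in: int, rng) -> float:
    n = len(y_row)
    Y = np.empty((B_in + 1, n))
    Y[0] = y_row
    Y[1:] = rng.permuted(np.tile(y_row, (B_in, 1)), axis=1)
    P = trend_pvals_rows(Y, X)
    logs = np.sort(np.log(P), axis=1)
    W = np.cumsum(logs, axis=1)[:, np.asarray(ks) - 1]
    h0 = (W <= W[0]).sum(axis=0) / (B_in + 1)
    return float(h0.min())


def double_permutation_artp_p(
    y: np.ndarray, X: np.ndarray, ks, B_outer: int, B_inner: int, seed: int
) -> float:
    """Nested double-permutation ARTP gene p-value (the slow, direct estimate).

    The observed MinP uses one inner permutation set; every outer permuted
    dataset gets a fresh inner set; the p-value is the (add-one) fraction of
    outer MinP values at least as extreme as the observed one.
    """
    rng = np.random.default_rng(seed)
    obs = _minp_observed(y, X, ks, B_inner, rng)
    hits = 0
    for _ in range(B_outer):
        yb = rng.permutation(y)
        if _minp_observed(yb, X, ks, B_inner, rng) <= obs:
            hits += 1
    return (hits + 1) / (B_outer + 1)
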