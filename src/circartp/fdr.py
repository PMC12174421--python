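"""Benjamini-Hochberg false discovery rate adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests


@dataclass
class FdrResult:
    ids: list
    pvalues: np.ndarray
    qvalues: np.ndarray


def fdr_adjust(pvals, ids=None) -> FdrResult:
    """Step-up BH q-values: q_(i) = min_{j >= i} m p_(j) / j, in input order.

    Accepts p-values in (0, 1]; an empty input yields an empty result.
    """
    p = np.asarray(list(pvals), dtype=float)
    ids = list(ids) if ids is not None else list(range(len(p)))
    if len(ids) != len(p):
        raise ValueError("ids and p-values differ in length")
    if p.size == 0:
        return FdrResult(ids=[], pvalues=p, qvalues=p.copy())
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return FdrResult(ids=ids, pvalues=p, qvalues=q)
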