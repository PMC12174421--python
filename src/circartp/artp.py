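"""Adaptive rank truncated product (ARTP) gene- and pathway-level tests.

The ARTP statistic for a set of m member p-values is built from the rank
truncated product W(K) = sum of the logs of the K smallest p-values, over a
small grid of truncation points K.  The significance of each W(K) is the
rank of the observed value within its permutation null, and the adaptive
statistic MinP is the smallest such rank over the K grid.  The single-layer
algorithm assesses MinP against the same permutation set: every permuted
dataset's MinP is computed with the identical rank machinery, so one layer
of permutations yields a valid empirical p-value (the observed row counts in
its own null, guaranteeing p >= 1/(B+1)).

Two permutation modes are provided:

* ``main`` — per-SNP association p-values; only case-control status is
  permuted, conditioning on genotypes and covariates.
* ``gxe`` — per-SNP dosage x exposure interaction p-values; the whole
  epidemiological record (status together with all covariates and the
  exposure) is permuted as one unit across individuals while genotype rows
  stay fixed, which preserves both the covariate-outcome structure and the
  SNP-SNP linkage disequilibrium.

Pathway-level inference reuses the same permutation set: each gene's MinP
vector is rank-transformed into per-permutation gene p-values, and the gene
machinery is applied once more with genes as items.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import chdtrc

from ._glm import (
    logistic_fit,
    score_add_pvalues,
    score_block_pvalue,
    wald_pvalue,
)
from .models import AdjustmentSet, CATEGORY_LEVELS

DEFAULT_B = 20_000


@dataclass(frozen=True)
class TruncationScheme:
    """Truncation grids: every top ``fraction`` of items, 5 points for genes
    (items = SNPs) and 10 for the pathway (items = genes)."""

    fraction: float = 0.05
    n_points_gene: int = 5
    n_points_pathway: int = 10

    def gene_points(self, m: int) -> list[int]:
        return truncation_points(m, self.n_points_gene, self.fraction)

    def pathway_points(self, m: int) -> list[int]:
        return truncation_points(m, self.n_points_pathway, self.fraction)


def truncation_points(m: int, n_points: int, fraction: float = 0.05) -> list[int]:
    """K_j = min(m, max(1, ceil(j * fraction * m))), de-duplicated ascending.

    For small sets the grid can collapse (m = 2 under the gene scheme gives
    {1}); that is the intended reading of "every top 5%" with a floor at one
    item.
    """
    if m < 1:
        raise ValueError("need at least one item")
    ks = []
    for j in range(1, n_points + 1):
        # round before ceil so exact-integer grid points survive float noise
        k = min(m, max(1, math.ceil(round(j * fraction * m, 9))))
        if not ks or k > ks[-1]:
            ks.append(k)
    return ks


def rtp_statistic(pvals: np.ndarray, k: int) -> float:
    """W(K): sum of natural logs of the K smallest p-values (smaller = stronger)."""
    pvals = np.asarray(pvals, dtype=float)
    if not (1 <= k <= pvals.size):
        raise ValueError(f"K={k} out of range for {pvals.size} p-values")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    smallest = np.partition(pvals, k - 1)[:k]
    return float(np.log(smallest).sum())


@dataclass
class PermutationPValueMatrix:
    """(B+1) x items p-value matrix; row 0 is the observed data.

    All rows share the same permutation indices across items (column
    coherence), which the ARTP rank machinery relies on.
    """

    values: np.ndarray
    snp_ids: list[str]
    mode: str
    B: int
    seed: int
    n_failed: int = 0
    n_imputed_dosages: int = 0

    def columns(self, snps) -> np.ndarray:
        idx = [self.snp_ids.index(s) for s in snps]
        return self.values[:, idx]


@dataclass
class GeneArtp:
    gene: str
    p: float
    best_k: int
    ks: list[int]
    minp: np.ndarray


@dataclass
class ArtpResult:
    genes: pd.DataFrame
    pathway_p: float
    pathway_best_k: int
    minp: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    mode: str = "main"
    B: int = 0
    seed: int = 0
    scheme: TruncationScheme = field(default_factory=TruncationScheme)
    n_failed: int = 0


def _empirical_ranks(W: np.ndarray) -> np.ndarray:
    """h[s, k] = #{t : W[t, k] <= W[s, k]} / (B+1), per truncation column."""
    B1 = W.shape[0]
    h = np.empty_like(W)
    for k in range(W.shape[1]):
        order = np.sort(W[:, k])
        h[:, k] = np.searchsorted(order, W[:, k], side="right") / B1
    return h


def artp_gene(
    pmat: np.ndarray, ks: list[int] | None = None,
    scheme: TruncationScheme = TruncationScheme(), gene: str = "gene",
) -> GeneArtp:
    """Single-layer ARTP for one gene's (B+1) x m p-value matrix."""
    pmat = np.asarray(pmat, dtype=float)
    if pmat.ndim != 2:
        raise ValueError("p-value matrix must be 2-D")
    B = pmat.shape[0] - 1
    if B < 19:
        warnings.warn(
            f"B={B} permutations give p-value resolution coarser than 0.05"
        )
    if (pmat <= 0).any() or (pmat > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    ks = scheme.gene_points(pmat.shape[1]) if ks is None else ks
    logs = np.sort(np.log(pmat), axis=1)
    cum = np.cumsum(logs, axis=1)
    W = cum[:, np.asarray(ks) - 1]
    h = _empirical_ranks(W)
    minp = h.min(axis=1)
    p = float(np.mean(minp <= minp[0]))
    best_k = int(ks[int(np.argmin(h[0]))])
    return GeneArtp(gene=gene, p=p, best_k=best_k, ks=list(ks), minp=minp)


def artp_pathway(
    gene_results: list[GeneArtp], scheme: TruncationScheme = TruncationScheme()
) -> GeneArtp:
    """Combine gene MinP vectors into the pathway-level ARTP.

    Each gene's MinP vector (from the same permutation set) is rank-transformed
    into per-permutation gene-level p-values; the gene machinery then runs
    once more with genes as items and the pathway truncation grid.
    """
    lengths = {len(g.minp) for g in gene_results}
    if len(lengths) != 1:
        raise ValueError("gene results mix different permutation counts")
    (B1,) = lengths
    gmat = np.empty((B1, len(gene_results)))
    for j, g in enumerate(gene_results):
        order = np.sort(g.minp)
        gmat[:, j] = np.searchsorted(order, g.minp, side="right") / B1
    ks = scheme.pathway_points(len(gene_results))
    return artp_gene(gmat, ks=ks, gene="pathway")


# ---------------------------------------------------------------------------
# Permutation p-value matrices


def _prepare(dosages, cohort, adjustment, exposure):
    """Complete-case arrays for the permutation engine.

    Rows with a missing status, covariate or exposure are dropped once (the
    permutation matrix must stay rectangular); missing dosages are
    mean-imputed with a logged count.
    """
    status = cohort["status"]
    adj = adjustment
    if exposure is not None:
        adj = (adj or AdjustmentSet()).with_exposure(exposure)
    parts = pd.DataFrame({"__y": status})
    if adj is not None:
        parts = parts.join(adj.design(cohort), how="left")
    parts = parts.dropna()
    idx = parts.index
    y = parts.pop("__y").to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(idx))] + [parts[c].to_numpy() for c in parts])
    X = dosages.loc[idx].to_numpy(dtype=float)
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        means = np.nanmean(X, axis=0)
        jj = np.where(np.isnan(X))
        X[jj] = np.where(np.isfinite(means), means, 0.0)[jj[1]]
    E = None
    df_int = 0
    if exposure is not None:
        if exposure in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[exposure]
            ref = adj.reference_for(exposure)
            vals = cohort.loc[idx, exposure]
            E = np.column_stack(
                [(vals == lvl).to_numpy(dtype=float) for lvl in levels if lvl != ref]
            )
        else:
            E = cohort.loc[idx, exposure].to_numpy(dtype=float)[:, None]
        df_int = E.shape[1]
    return y, Z, X, E, df_int, n_imputed


def build_permutation_pvalues(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    mode: str = "main",
    exposure: str | None = None,
    adjustment: AdjustmentSet | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    backend: str = "refit",
) -> PermutationPValueMatrix:
    """Observed plus B permuted per-SNP p-value rows.

    ``main`` mode reports association p-values (Wald under the refit backend,
    Rao score under the score backend) and permutes case-control status only.
    ``gxe`` mode reports dosage x exposure interaction p-values (LRT under
    refit, block score under score) and permutes the full epidemiological
    record as one unit, leaving genotypes untouched.  Failed or undefined
    fits are recorded as p = 1 with a counter.  Deterministic given the seed.
    """
    if mode not in ("main", "gxe"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "gxe" and exposure is None:
        raise ValueError("gxe mode needs an exposure name")
    if B < 0:
        raise ValueError("B must be >= 0")
    y, Z, X, E, df_int, n_imputed = _prepare(
        dosages, cohort, adjustment, exposure if mode == "gxe" else None
    )
    n, m = X.shape
    rng = np.random.default_rng(seed)
    values = np.ones((B + 1, m))
    n_failed = 0
    base_fit = logistic_fit(Z, y)
    for s in range(B + 1):
        if s == 0:
            perm = np.arange(n)
        else:
            perm = rng.permutation(n)
        ys = y[perm]
        if mode == "main":
            Zs, Es = Z, None
        else:
            Zs = Z[perm]
            Es = E[perm]
        null_fit = logistic_fit(Zs, ys, start=base_fit.beta)
        if not null_fit.converged:
            null_fit = logistic_fit(Zs, ys)
        if mode == "main":
            if backend == "score":
                ps = score_add_pvalues(Zs, ys, X, null_fit)
            elif backend == "refit":
                ps = np.empty(m)
                start = np.append(null_fit.beta, 0.0)
                for j in range(m):
                    fit = logistic_fit(
                        np.column_stack([Zs, X[:, j]]), ys, start=start
                    )
                    ps[j] = wald_pvalue(fit, -1) if fit.ok else np.nan
            else:
                raise ValueError(f"unknown backend {backend!r}")
        else:
            ps = np.empty(m)
            start_red = np.append(null_fit.beta, 0.0)
            for j in range(m):
                x = X[:, j]
                reduced = np.column_stack([Zs, x])
                red_fit = logistic_fit(reduced, ys, start=start_red)
                if not red_fit.ok:
                    ps[j] = np.nan
                    continue
                C = x[:, None] * Es
                if backend == "score":
                    ps[j] = score_block_pvalue(reduced, ys, C, red_fit)
                elif backend == "refit":
                    full = np.column_stack([reduced, C])
                    full_fit = logistic_fit(
                        full, ys, start=np.append(red_fit.beta, np.zeros(df_int))
                    )
                    if not full_fit.ok:
                        ps[j] = np.nan
                        continue
                    stat = max(0.0, 2.0 * (full_fit.loglik - red_fit.loglik))
                    ps[j] = float(chdtrc(df_int, stat))
                else:
                    raise ValueError(f"unknown backend {backend!r}")
        bad = ~np.isfinite(ps)
        n_failed += int(bad.sum())
        ps[bad] = 1.0
        values[s] = np.clip(ps, np.nextafter(0.0, 1.0), 1.0)
    return PermutationPValueMatrix(
        values=values,
        snp_ids=list(dosages.columns),
        mode=mode,
        B=B,
        seed=seed,
        n_failed=n_failed,
        n_imputed_dosages=n_imputed,
    )


def run_artp(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    annotation: pd.DataFrame,
    mode: str = "main",
    exposure: str | None = None,
    adjustment: AdjustmentSet | None = None,
    scheme: TruncationScheme = TruncationScheme(),
    B: int = DEFAULT_B,
    seed: int = 0,
    backend: str = "refit",
) -> ArtpResult:
    """Full gene + pathway ARTP from genotypes, cohort and SNP-gene map.

    ``annotation`` needs columns ``snp`` and ``gene``; a SNP inside several
    overlapping gene windows contributes to each of its genes, while the
    pathway level counts every gene once.
    """
    ann = annotation[annotation["snp"].isin(dosages.columns)]
    unmapped = set(dosages.columns) - set(ann["snp"])
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} SNPs have no gene annotation, e.g. {sorted(unmapped)[:3]}"
        )
    matrix = build_permutation_pvalues(
        dosages, cohort, mode=mode, exposure=exposure,
        adjustment=adjustment, B=B, seed=seed, backend=backend,
    )
    gene_results: list[GeneArtp] = []
    for gene, sub in ann.groupby("gene", sort=True):
        snps = list(sub["snp"])
        res = artp_gene(matrix.columns(snps), scheme=scheme, gene=gene)
        gene_results.append(res)
    pathway = artp_pathway(gene_results, scheme=scheme)
    genes = pd.DataFrame(
        {
            "gene": [g.gene for g in gene_results],
            "n_snps": [len(ann[ann["gene"] == g.gene]) for g in gene_results],
            "best_k": [g.best_k for g in gene_results],
            "p_artp": [g.p for g in gene_results],
        }
    )
    return ArtpResult(
        genes=genes,
        pathway_p=pathway.p,
        pathway_best_k=pathway.best_k,
        minp={g.gene: g.minp for g in gene_results},
        mode=mode,
        B=B,
        seed=seed,
        scheme=scheme,
        n_failed=matrix.n_failed,
    )
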