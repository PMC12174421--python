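"""Genotype and sample quality control with an auditable exclusion ledger.

Filter order is fixed: for SNPs, call rate -> Hardy-Weinberg -> reference
concordance (user-supplied ids) -> minor-allele frequency in controls; for
samples, genotyping failure -> consent withdrawal -> PCA outliers.  Each
stage records exactly which ids it removed (first-failure attribution), and
the ledger arithmetic ``n_input - sum(excluded) = n_remaining`` is enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class QcThresholds:
    call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_alpha: float = 1e-5
    pca_sd: float = 6.0
    pca_components: int = 2

    def __post_init__(self):
        if not (0.0 < self.call_rate_min <= 1.0):
            raise ValueError("call_rate_min must be in (0, 1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0, 1)")
        if self.pca_sd <= 0 or self.pca_components < 1:
            raise ValueError("pca_sd must be > 0 and pca_components >= 1")


@dataclass
class QcStage:
    name: str
    n_excluded: int
    ids: tuple = ()


@dataclass
class QcReport:
    """Ordered exclusion ledger with enforced accounting."""

    n_input: int
    stages: list[QcStage] = field(default_factory=list)

    def add(self, name: str, excluded) -> None:
        if isinstance(excluded, int):
            stage = QcStage(name, excluded)
        else:
            ids = tuple(excluded)
            stage = QcStage(name, len(ids), ids)
        if stage.n_excluded < 0:
            raise ValueError(f"negative exclusion count at stage {name!r}")
        if self.n_remaining - stage.n_excluded < 0:
            raise ValueError(
                f"inconsistent ledger: stage {name!r} excludes {stage.n_excluded} "
                f"but only {self.n_remaining} remain"
            )
        self.stages.append(stage)

    @property
    def n_remaining(self) -> int:
        return self.n_input - sum(s.n_excluded for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        remaining = self.n_input
        for s in self.stages:
            remaining -= s.n_excluded
            rows.append({"stage": s.name, "n_excluded": s.n_excluded,
                         "n_remaining": remaining})
        return pd.DataFrame(rows, columns=["stage", "n_excluded", "n_remaining"])


def sample_ledger(n_input: int, exclusions) -> QcReport:
    """Build a ledger from staged ``(name, count-or-ids)`` exclusions."""
    report = QcReport(n_input=n_input)
    for name, excluded in exclusions:
        report.add(name, excluded)
    return report


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests


def hwe_exact_pvalue(
    n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False
) -> float:
    """Exact Hardy-Weinberg test by conditional enumeration.

    Conditions on the observed allele counts and sums the probability of all
    heterozygote configurations no more probable than the observed one
    (two-sided).  Monomorphic SNPs return p = 1 by convention.

    ``midp=True`` subtracts half the observed configuration's probability
    (the mid-p correction): the plain exact p is discrete and conservative,
    which is what a filter wants, while the mid-p version is the one to use
    when checking calibration, since it is uniform under the null up to
    discreteness that vanishes with sample size.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    rare = 2 * n_hom_alt + n_het
    rare = min(rare, 2 * n - rare)
    if rare == 0:
        return 1.0
    obs_het = n_het
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h) up to a constant: n! / (h! ((rare-h)/2)! ((2n-rare-h)/2)!) * 2^h
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1.0)
        - gammaln((rare - hets) / 2.0 + 1.0)
        - gammaln((2 * n - rare - hets) / 2.0 + 1.0)
    )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[np.searchsorted(hets, obs_het)]
    # relative tolerance absorbs float noise on exact probability ties
    tail = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(1.0, tail))


def hwe_chi2_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df Pearson chi-square Hardy-Weinberg test."""
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError(f"negative genotype count: {counts}")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    q = (2 * n_hom_alt + n_het) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, 1))


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact") -> float:
    if method == "exact":
        return hwe_exact_pvalue(n_hom_ref, n_het, n_hom_alt)
    if method == "chi2":
        return hwe_chi2_pvalue(n_hom_ref, n_het, n_hom_alt)
    raise ValueError(f"unknown HWE method {method!r}")


def _genotype_counts(col: pd.Series) -> tuple[int, int, int]:
    vals = col.dropna().round().astype(int)
    return int((vals == 0).sum()), int((vals == 1).sum()), int((vals == 2).sum())


# ---------------------------------------------------------------------------
# SNP-level filters


def call_rate_filter(
    dosages: pd.DataFrame, threshold: float = 0.95
) -> tuple[list[str], list[str]]:
    """Exclude SNPs with non-missing fraction strictly below ``threshold``."""
    if dosages.shape[0] == 0 or dosages.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("call-rate threshold must be in (0, 1]")
    rate = dosages.notna().mean(axis=0)
    excluded = list(rate.index[rate < threshold])
    kept = list(rate.index[rate >= threshold])
    return kept, excluded


def hwe_filter(
    dosages: pd.DataFrame,
    alpha: float = 1e-5,
    method: str = "exact",
    status: pd.Series | None = None,
    controls_only: bool = False,
) -> tuple[list[str], list[str]]:
    """Exclude SNPs failing Hardy-Weinberg at ``p < alpha``.

    Tested in all individuals by default; pass ``controls_only=True`` with a
    status vector to restrict to controls.
    """
    data = dosages
    if controls_only:
        if status is None:
            raise ValueError("controls_only requires a status vector")
        data = dosages.loc[status.reindex(dosages.index) == 0]
    kept, excluded = [], []
    for snp in data.columns:
        counts = _genotype_counts(data[snp])
        if sum(counts) == 0:
            excluded.append(snp)
            continue
        p = hwe_test(*counts, method=method)
        (excluded if p < alpha else kept).append(snp)
    return kept, excluded


def maf_filter(
    dosages: pd.DataFrame, status: pd.Series, threshold: float = 0.01
) -> tuple[list[str], list[str]]:
    """Exclude SNPs with minor-allele frequency in controls strictly < threshold.

    MAF is the allele count over twice the number of non-missing control
    genotypes; SNPs with no called control genotypes are excluded.
    """
    status = status.reindex(dosages.index)
    controls = dosages.loc[status == 0]
    if controls.shape[0] == 0:
        raise ValueError("no control individuals for MAF computation")
    kept, excluded = [], []
    for snp in controls.columns:
        col = controls[snp].dropna()
        if len(col) == 0:
            excluded.append(snp)
            continue
        freq = col.sum() / (2 * len(col))
        maf = min(freq, 1.0 - freq)
        (excluded if maf < threshold else kept).append(snp)
    return kept, excluded


# ---------------------------------------------------------------------------
# Sample-level screens


def pca_outliers(
    dosages: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Flag individuals beyond ``pca_sd`` SDs on any leading principal component.

    Dosages are mean-imputed and standardised per SNP before the SVD; the PC
    scores are returned so they can also enter the regression adjustment.
    """
    if dosages.shape[0] < 3 or dosages.shape[1] < 2:
        raise ValueError("PCA needs at least 3 individuals and 2 SNPs")
    X = dosages.to_numpy(dtype=float)
    means = np.nanmean(X, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = means[idx[1]]
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    k = thresholds.pca_components
    if X.shape[1] < k:
        raise ValueError(
            f"rank-deficient genotype matrix: {X.shape[1]} informative SNPs "
            f"cannot support {k} principal components"
        )
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    if (S[:k] <= 1e-10).any():
        raise ValueError("rank-deficient genotype matrix: degenerate leading PCs")
    scores = U[:, :k] * S[:k]
    center = scores.mean(axis=0)
    spread = scores.std(axis=0)
    flagged = (np.abs(scores - center) > thresholds.pca_sd * spread).any(axis=1)
    score_df = pd.DataFrame(
        scores, index=dosages.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return list(dosages.index[flagged]), score_df


def ibs_identity_screen(
    dosages: pd.DataFrame, threshold: float = 0.9, max_pairs: int = 2_000_000
) -> list[tuple[str, str, float]]:
    """Pairwise identity-by-state proportion screen for duplicate samples.

    Returns pairs with mean IBS fraction (shared alleles / 2) above the
    threshold.  A plain O(n^2 m) scan; intended for cohort-sized inputs.
    """
    X = dosages.to_numpy(dtype=float)
    n = X.shape[0]
    if n * (n - 1) // 2 > max_pairs:
        raise ValueError("too many pairs for the identity screen")
    ids = list(dosages.index)
    hits = []
    for i in range(n):
        diff = np.abs(X[i + 1 :] - X[i])  # 0, 1 or 2 allele mismatches
        ok = ~np.isnan(diff)
        with np.errstate(invalid="ignore"):
            ibs = 1.0 - np.nansum(diff, axis=1) / (2.0 * ok.sum(axis=1))
        for j, val in enumerate(ibs, start=i + 1):
            if np.isfinite(val) and val > threshold:
                hits.append((ids[i], ids[j], float(val)))
    return hits


# ---------------------------------------------------------------------------
# Orchestrated QC


@dataclass
class QcResult:
    dosages: pd.DataFrame
    cohort: pd.DataFrame
    snp_report: QcReport
    sample_report: QcReport
    pc_scores: pd.DataFrame


def run_qc(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    hwe_method: str = "exact",
    hwe_controls_only: bool = False,
    concordance_exclude: tuple = (),
    withdrawal_ids: tuple = (),
) -> QcResult:
    """Apply the full filter cascade and return data plus both ledgers.

    ``concordance_exclude`` holds SNP ids failing an external reference
    concordance check; ``withdrawal_ids`` holds individuals who withdrew
    consent.  Both enter the ledger as their own stages.
    """
    status = cohort["status"]
    sample_report = QcReport(n_input=dosages.shape[0])
    all_missing = dosages.index[dosages.isna().all(axis=1)]
    sample_report.add("genotyping_failure", list(all_missing))
    kept_ind = dosages.index.difference(all_missing, sort=False)
    withdrawals = [i for i in withdrawal_ids if i in set(kept_ind)]
    sample_report.add("withdrawal", withdrawals)
    kept_ind = kept_ind.difference(pd.Index(withdrawals), sort=False)
    data = dosages.loc[kept_ind]
    status = status.reindex(kept_ind)

    snp_report = QcReport(n_input=data.shape[1])
    kept, excluded = call_rate_filter(data, thresholds.call_rate_min)
    snp_report.add("call_rate", excluded)
    data = data[kept]
    kept, excluded = hwe_filter(
        data, thresholds.hwe_alpha, method=hwe_method,
        status=status, controls_only=hwe_controls_only,
    )
    snp_report.add("hwe", excluded)
    data = data[kept]
    concordant_fail = [s for s in concordance_exclude if s in data.columns]
    snp_report.add("reference_concordance", concordant_fail)
    data = data.drop(columns=concordant_fail)
    kept, excluded = maf_filter(data, status, thresholds.maf_min)
    snp_report.add("maf_controls", excluded)
    data = data[kept]

    if data.shape[1] >= 2 and data.shape[0] >= 3:
        flagged, pc_scores = pca_outliers(data, thresholds)
    else:
        warnings.warn("too few SNPs/individuals for the PCA outlier screen")
        flagged, pc_scores = [], pd.DataFrame(index=data.index)
    sample_report.add("pca_outlier", flagged)
    keep_final = data.index.difference(pd.Index(flagged), sort=False)
    return QcResult(
        dosages=data.loc[keep_final],
        cohort=cohort.loc[keep_final],
        snp_report=snp_report,
        sample_report=sample_report,
        pc_scores=pc_scores.loc[keep_final] if len(pc_scores) else pc_scores,
    )
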