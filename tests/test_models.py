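"""Logistic association fits, interaction LRTs, stratified ORs and LD."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from circartp.models import (
    AdjustmentSet,
    fit_additive,
    interaction_lrt,
    ld_r2,
    stratified_or,
)
from circartp.simulate import (
    EffectModel,
    PanelSpec,
    simulate_covariates,
    simulate_genotypes,
    simulate_outcome,
)


def _series(values, prefix="i"):
    return pd.Series(values, index=[f"{prefix}{k}" for k in range(len(values))])


def test_crude_or_equals_cross_product_ratio():
    """Binary dosage without covariates: the MLE odds ratio is the 2x2
    cross-product (14*473)/(9*449)."""
    dosage = _series([1.0] * 14 + [0.0] * 449 + [1.0] * 9 + [0.0] * 473)
    status = _series([1] * 463 + [0] * 482)
    r = fit_additive(dosage, status)
    expected = (14 * 473) / (9 * 449)
    assert r.converged
    assert r.or_ == pytest.approx(expected, rel=1e-6)
    assert r.or_ == pytest.approx(np.exp(r.beta), abs=1e-12)
    assert r.ci95[0] == pytest.approx(np.exp(r.beta - 1.959963984540054 * r.se), rel=1e-9)


def test_null_wald_pvalues_uniform():
    """Association p-values are uniform when status is independent of dosage."""
    panel = PanelSpec(genes=(("G", 500),), ld_rho=0.0, seed=10, maf_range=(0.1, 0.45))
    d = simulate_genotypes(panel, 5000).dosages
    rng = np.random.default_rng(11)
    status = pd.Series(rng.integers(0, 2, size=5000), index=d.index)
    pvals = [fit_additive(d[c], status).p for c in d.columns]
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_separation_is_flagged_not_raised():
    dosage = _series([2.0] * 50 + [0.0] * 50)
    status = _series([1] * 50 + [0] * 50)
    r = fit_additive(dosage, status)
    assert not r.converged
    assert np.isnan(r.p)


def test_monomorphic_snp_returns_structured_result():
    dosage = _series([1.0] * 80)
    status = _series([1] * 40 + [0] * 40)
    r = fit_additive(dosage, status)
    assert r.note == "monomorphic" and not r.converged


def test_missing_dosage_dropped_pairwise():
    dosage = _series([np.nan] * 10 + [1.0] * 45 + [0.0] * 45)
    status = _series([1] * 50 + [0] * 50)
    r = fit_additive(dosage, status)
    assert r.n_used == 90


def test_interaction_df_for_three_level_exposure(null_cohort):
    genotypes, cohort = null_cohort
    r = interaction_lrt(
        genotypes.dosages["GENEA_snp001"], cohort["smoking"], cohort["status"],
        AdjustmentSet(categorical=("smoking",), continuous=()), cohort,
    )
    assert r.df == 2
    assert r.lrt_stat >= 0


def test_interaction_df_for_continuous_exposure(null_cohort):
    genotypes, cohort = null_cohort
    r = interaction_lrt(
        genotypes.dosages["GENEA_snp001"], cohort["bmi"], cohort["status"],
        AdjustmentSet(categorical=(), continuous=("bmi",)), cohort,
    )
    assert r.df == 1


def test_lrt_invariant_to_exposure_reference_level(null_cohort):
    genotypes, cohort = null_cohort
    args = (genotypes.dosages["GENEA_snp002"], cohort["smoking"], cohort["status"])
    a = interaction_lrt(
        *args, AdjustmentSet(categorical=("smoking",), continuous=()), cohort
    )
    b = interaction_lrt(
        *args,
        AdjustmentSet(
            categorical=("smoking",), continuous=(),
            references=(("smoking", "current"),),
        ),
        cohort,
    )
    assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-6)
    assert a.df == b.df


def test_interaction_null_pvalues_uniform():
    """Interaction LRT p-values are uniform without a generating interaction."""
    rng = np.random.default_rng(3)
    pvals = []
    n = 600
    for _ in range(300):
        dosage = _series(rng.binomial(2, 0.3, size=n).astype(float))
        smoking = _series(rng.choice(["never", "former", "current"], size=n))
        smoking.name = "smoking"
        status = _series(rng.integers(0, 2, size=n))
        r = interaction_lrt(
            dosage, smoking, status,
            AdjustmentSet(categorical=("smoking",), continuous=()),
        )
        if r.converged:
            pvals.append(r.p)
    assert len(pvals) > 280
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_interaction_power_under_stratum_or_pattern():
    """The Table-5-style pattern (never 0.74 / former 2.79 / current 0.38,
    EAF 0.13) is detectable at n=945: median interaction p < 0.05."""
    target = "G_snp001"
    panel = PanelSpec(genes=(("G", 1),), fixed_mafs={target: 0.13}, seed=2)
    model = EffectModel(
        snp_betas={target: np.log(0.74)},
        interaction_betas={
            (target, "smoking", "former"): np.log(2.79 / 0.74),
            (target, "smoking", "current"): np.log(0.38 / 0.74),
        },
    )
    rng = np.random.default_rng(41)
    pvals = []
    for _ in range(15):
        s = int(rng.integers(2**31 - 10))
        g = simulate_genotypes(panel, 945, seed=s)
        cov = simulate_covariates(945, seed=s + 1)
        cohort = simulate_outcome(g, cov, model, seed=s + 2)
        r = interaction_lrt(
            g.dosages[target], cohort["smoking"], cohort["status"],
            AdjustmentSet(categorical=("smoking",), continuous=()), cohort,
        )
        pvals.append(r.p)
    assert np.median(pvals) < 0.05


def test_lrt_uses_identical_analysis_sets_with_missing_exposure(null_cohort):
    """Rows with a missing exposure leave both LRT models, so the statistic
    matches a manual two-fit computation on the complete rows."""
    import statsmodels.api as sm

    genotypes, cohort = null_cohort
    cohort = cohort.copy()
    smoking = cohort["smoking"].copy()
    smoking.iloc[:25] = np.nan
    cohort["smoking"] = smoking
    dosage = genotypes.dosages["GENEB_snp001"]
    r = interaction_lrt(
        dosage, cohort["smoking"], cohort["status"],
        AdjustmentSet(categorical=("smoking",), continuous=()), cohort,
    )
    keep = smoking.notna()
    y = cohort.loc[keep, "status"].to_numpy(dtype=float)
    x = dosage[keep].to_numpy()
    former = (smoking[keep] == "former").to_numpy(dtype=float)
    current = (smoking[keep] == "current").to_numpy(dtype=float)
    const = np.ones(keep.sum())
    reduced = np.column_stack([const, former, current, x])
    full = np.column_stack([reduced, x * former, x * current])
    ll_r = sm.Logit(y, reduced).fit(disp=0).llf
    ll_f = sm.Logit(y, full).fit(disp=0).llf
    assert r.lrt_stat == pytest.approx(2 * (ll_f - ll_r), abs=1e-6)


def test_stratified_or_skips_empty_stratum(null_cohort):
    genotypes, cohort = null_cohort
    cohort = cohort.copy()
    stratum = cohort["smoking"].copy()
    cohort.loc[stratum == "current", "status"] = 1  # one-class stratum
    with pytest.warns(UserWarning, match="lacks both outcome classes"):
        out = stratified_or(
            genotypes.dosages["GENEA_snp001"], stratum, cohort["status"],
            AdjustmentSet(categorical=(), continuous=()), cohort,
        )
    assert "current" not in set(out["stratum"])


def test_multi_loci_rank_deficiency_detected(null_cohort):
    genotypes, cohort = null_cohort
    d = genotypes.dosages[["GENEA_snp001"]].copy()
    d["dup"] = d["GENEA_snp001"]
    out = stratified_or(
        d, cohort["smoking"], cohort["status"],
        AdjustmentSet(categorical=(), continuous=()), cohort, joint=True,
    )
    assert (out["note"] == "rank_deficient").all()
    assert not out["converged"].any()


def test_null_stratified_cis_cover_one(null_cohort):
    genotypes, cohort = null_cohort
    out = stratified_or(
        genotypes.dosages, cohort["smoking"], cohort["status"],
        AdjustmentSet(categorical=(), continuous=()), cohort,
    )
    ok = out[out["converged"]]
    cover = ((ok["ci_low"] <= 1.0) & (1.0 <= ok["ci_high"])).mean()
    assert cover > 0.8


class TestLdR2:
    def test_identical_vectors(self):
        a = _series([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        assert ld_r2(a, a.copy()) == 1.0

    def test_independent_snps_near_zero(self):
        panel = PanelSpec(genes=(("G", 2),), ld_rho=0.0, seed=14)
        d = simulate_genotypes(panel, 20000).dosages
        assert ld_r2(d.iloc[:, 0], d.iloc[:, 1]) < 0.003

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        a = _series(rng.binomial(2, 0.3, 500).astype(float))
        b = _series(rng.binomial(2, 0.4, 500).astype(float))
        assert ld_r2(a, b) == pytest.approx(ld_r2(2 - a, b), abs=1e-12)

    def test_constant_input_is_missing(self):
        a = _series([1.0] * 10)
        b = _series([0.0, 1.0] * 5)
        assert np.isnan(ld_r2(a, b))
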