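"""ARTP machinery: truncation grids, rank transforms, permutation engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, spearmanr

from circartp.artp import (
    TruncationScheme,
    artp_gene,
    artp_pathway,
    build_permutation_pvalues,
    rtp_statistic,
    run_artp,
    truncation_points,
)
from circartp.models import AdjustmentSet, fit_additive, interaction_lrt


class TestTruncationPoints:
    def test_gene_grid_for_largest_gene(self):
        assert truncation_points(285, 5) == [15, 29, 43, 57, 72]

    def test_pathway_grid_for_23_genes(self):
        assert truncation_points(23, 10) == [2, 3, 4, 5, 6, 7, 9, 10, 11, 12]

    def test_tiny_gene_collapses_to_single_point(self):
        assert truncation_points(2, 5) == [1]
        assert truncation_points(3, 5) == [1]

    def test_single_item(self):
        assert truncation_points(1, 5) == [1]

    def test_zero_items_rejected(self):
        with pytest.raises(ValueError):
            truncation_points(0, 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=600), st.integers(min_value=1, max_value=12))
    def test_grid_properties(self, m, n_points):
        ks = truncation_points(m, n_points)
        assert ks, "grid never empty"
        assert all(1 <= k <= m for k in ks)
        assert all(b > a for a, b in zip(ks, ks[1:])), "strictly increasing"


class TestRtpStatistic:
    def test_product_of_two_smallest(self):
        w = rtp_statistic(np.array([0.1, 0.01, 0.5]), 2)
        assert w == pytest.approx(np.log(0.01) + np.log(0.1), abs=1e-12)

    def test_k_one_is_log_min(self):
        assert rtp_statistic(np.array([0.3, 0.2, 0.9]), 1) == pytest.approx(np.log(0.2))

    def test_all_ones_give_zero(self):
        for k in (1, 2, 3):
            assert rtp_statistic(np.ones(3), k) == 0.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            rtp_statistic(np.array([0.5]), 2)


class TestArtpGene:
    def test_rank_transform_is_a_permutation_of_the_grid(self):
        rng = np.random.default_rng(0)
        pmat = rng.uniform(1e-6, 1, size=(200, 7))
        res = artp_gene(pmat, ks=[1, 2, 3])
        # continuous W values: MinP over a 1-point grid is the exact rank set
        one_k = artp_gene(pmat, ks=[2])
        expected = np.arange(1, 201) / 200
        assert np.allclose(np.sort(one_k.minp), expected)
        assert res.p >= 1 / 200

    def test_observed_most_extreme_attains_floor(self):
        rng = np.random.default_rng(1)
        pmat = rng.uniform(0.2, 1, size=(100, 4))
        pmat[0] = 1e-8
        res = artp_gene(pmat, ks=[1, 2, 4])
        assert res.p == pytest.approx(1 / 100)

    def test_single_snp_gene_equals_plain_permutation_p(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(0, 1, size=(500, 1))
        res = artp_gene(col)
        plain = np.mean(col[:, 0] <= col[0, 0])
        assert abs(res.p - plain) <= 1 / 500

    def test_low_resolution_warns(self):
        with pytest.warns(UserWarning, match="resolution"):
            artp_gene(np.random.default_rng(3).uniform(0.1, 1, (10, 2)))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            artp_gene(np.zeros((30, 2)))


class TestArtpPathway:
    def test_single_gene_pathway_matches_gene_p(self):
        rng = np.random.default_rng(4)
        pmat = rng.uniform(1e-4, 1, size=(300, 5))
        gene = artp_gene(pmat)
        path = artp_pathway([gene])
        assert abs(path.p - gene.p) <= 1 / 300

    def test_resolution_floor(self):
        rng = np.random.default_rng(5)
        genes = [artp_gene(rng.uniform(1e-4, 1, size=(100, 3))) for _ in range(4)]
        assert artp_pathway(genes).p >= 1 / 100

    def test_mismatched_permutation_counts_rejected(self):
        rng = np.random.default_rng(6)
        a = artp_gene(rng.uniform(0.01, 1, (100, 2)))
        b = artp_gene(rng.uniform(0.01, 1, (50, 2)))
        with pytest.raises(ValueError, match="permutation counts"):
            artp_pathway([a, b])


class TestPermutationMatrix:
    def test_b_zero_is_just_the_observed_row(self, status_only_cohort):
        genotypes, cohort = status_only_cohort
        m = build_permutation_pvalues(
            genotypes.dosages, cohort, B=0, seed=1, backend="score"
        )
        assert m.values.shape == (1, 3)

    def test_fixed_seed_is_bit_identical(self, status_only_cohort):
        genotypes, cohort = status_only_cohort
        a = build_permutation_pvalues(genotypes.dosages, cohort, B=30, seed=9,
                                      backend="score")
        b = build_permutation_pvalues(genotypes.dosages, cohort, B=30, seed=9,
                                      backend="score")
        assert np.array_equal(a.values, b.values)

    def test_refit_backend_matches_statsmodels_wald(self, null_cohort):
        genotypes, cohort = null_cohort
        adj = AdjustmentSet(categorical=("smoking",), continuous=("bmi",))
        m = build_permutation_pvalues(
            genotypes.dosages, cohort, adjustment=adj, B=0, backend="refit"
        )
        for j, snp in enumerate(genotypes.dosages.columns):
            ref = fit_additive(genotypes.dosages[snp], cohort["status"], adj, cohort)
            assert m.values[0, j] == pytest.approx(ref.p, abs=1e-5)

    def test_gxe_refit_backend_matches_interaction_lrt(self, null_cohort):
        genotypes, cohort = null_cohort
        adj = AdjustmentSet(categorical=("smoking",), continuous=())
        m = build_permutation_pvalues(
            genotypes.dosages, cohort, mode="gxe", exposure="smoking",
            adjustment=adj, B=0, backend="refit",
        )
        for j, snp in enumerate(genotypes.dosages.columns):
            ref = interaction_lrt(
                genotypes.dosages[snp], cohort["smoking"], cohort["status"],
                adj, cohort,
            )
            assert m.values[0, j] == pytest.approx(ref.p, abs=1e-5)

    def test_score_and_refit_backends_rank_agree(self, null_cohort):
        genotypes, cohort = null_cohort
        adj = AdjustmentSet(categorical=("smoking",), continuous=())
        kw = dict(adjustment=adj, B=30, seed=4)
        a = build_permutation_pvalues(genotypes.dosages, cohort, backend="score", **kw)
        b = build_permutation_pvalues(genotypes.dosages, cohort, backend="refit", **kw)
        rho = spearmanr(a.values.ravel(), b.values.ravel()).statistic
        assert rho > 0.99

    def test_gxe_permutation_leaves_genotypes_untouched(self, null_cohort):
        genotypes, cohort = null_cohort
        before = genotypes.dosages.copy()
        r2_before = np.corrcoef(before.to_numpy().T) ** 2
        build_permutation_pvalues(
            genotypes.dosages, cohort, mode="gxe", exposure="smoking",
            adjustment=AdjustmentSet(categorical=("smoking",), continuous=()),
            B=10, seed=0, backend="score",
        )
        pd.testing.assert_frame_equal(before, genotypes.dosages)
        r2_after = np.corrcoef(genotypes.dosages.to_numpy().T) ** 2
        assert np.array_equal(r2_before, r2_after)

    def test_gxe_mode_requires_exposure(self, status_only_cohort):
        genotypes, cohort = status_only_cohort
        with pytest.raises(ValueError, match="exposure"):
            build_permutation_pvalues(genotypes.dosages, cohort, mode="gxe")

    def test_observed_p_rank_uniform_under_null(self):
        """Exchangeability: the observed p-value falls uniformly within its
        own permutation distribution across simulated null datasets."""
        from circartp.simulate import PanelSpec, simulate_genotypes

        panel = PanelSpec(genes=(("G", 3),), ld_rho=0.4, seed=1,
                          maf_range=(0.2, 0.4))
        rng = np.random.default_rng(7)
        ranks = []
        for _ in range(150):
            s = int(rng.integers(2**31 - 10))
            genotypes = simulate_genotypes(panel, 80, seed=s)
            cohort = pd.DataFrame(
                {"status": rng.integers(0, 2, size=80)},
                index=genotypes.dosages.index,
            )
            m = build_permutation_pvalues(
                genotypes.dosages, cohort, B=99, seed=s + 1, backend="score"
            )
            col = m.values[:, 0]
            ranks.append(np.mean(col <= col[0]))
        assert kstest(ranks, "uniform").pvalue > 0.01


class TestRunArtp:
    def test_deterministic_full_result(self, null_cohort):
        genotypes, cohort = null_cohort
        kw = dict(
            annotation=genotypes.snps[["snp", "gene"]],
            adjustment=AdjustmentSet(categorical=("smoking",), continuous=()),
            B=50, seed=3, backend="score",
        )
        a = run_artp(genotypes.dosages, cohort, **kw)
        b = run_artp(genotypes.dosages, cohort, **kw)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert a.pathway_p == b.pathway_p

    def test_multi_window_snp_contributes_to_both_genes(self, null_cohort):
        genotypes, cohort = null_cohort
        ann = genotypes.snps[["snp", "gene"]]
        extra = pd.DataFrame({"snp": ["GENEA_snp003"], "gene": ["GENEB"]})
        ann = pd.concat([ann, extra], ignore_index=True)
        res = run_artp(
            genotypes.dosages, cohort, ann, B=30, seed=2, backend="score",
            adjustment=None,
        )
        counts = res.genes.set_index("gene")["n_snps"]
        assert counts["GENEB"] == 3  # its own 2 SNPs + the shared one

    def test_unmapped_snp_rejected(self, null_cohort):
        genotypes, cohort = null_cohort
        ann = genotypes.snps[["snp", "gene"]].iloc[:-1]
        with pytest.raises(ValueError, match="no gene annotation"):
            run_artp(genotypes.dosages, cohort, ann, B=5, backend="score")
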