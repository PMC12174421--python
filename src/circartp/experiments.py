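"""Reproducible simulation studies built on the package's own pipeline.

These routines generate synthetic cohorts under stated effect models, run
the QC/regression/ARTP machinery, and summarise operating characteristics
(null calibration, interaction power, confidence-interval coverage).  They
are what the repository's acceptance script and the heavier tests execute;
problem sizes are chosen so each study runs in minutes on one CPU while
keeping the study's stated sample sizes (463 cases / 482 controls, B = 199
permutations) intact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .artp import TruncationScheme, run_artp
from .models import AdjustmentSet, stratified_or, stratum_adjustment
from .simulate import (
    EffectModel,
    PanelSpec,
    default_panel,
    sample_case_control,
    simulate_covariates,
    simulate_genotypes,
    simulate_outcome,
)

# Lean adjustment used inside permutation loops: the matching variables plus
# the confounders of the stratified-OR models.
STUDY_ADJUSTMENT = AdjustmentSet(
    categorical=("age_band", "residence", "menarche", "parity", "oc_use", "smoking"),
    continuous=("bmi",),
)


def _simulate_study(panel, model, n_cases, n_controls, seed, population=2600):
    genotypes = simulate_genotypes(panel, population, seed=seed)
    covariates = simulate_covariates(population, seed=seed + 1)
    cohort = simulate_outcome(genotypes, covariates, model, seed=seed + 2)
    return sample_case_control(cohort, genotypes, n_cases, n_controls, seed=seed + 3)


def null_calibration(
    n_replicates: int = 200,
    B: int = 199,
    seed: int = 0,
    n_cases: int = 463,
    n_controls: int = 482,
    panel: PanelSpec | None = None,
) -> dict:
    """Type-I error of the pathway ARTP and uniformity of gene-level p-values.

    Replicate case-control datasets are drawn under a global null (no SNP
    effects) from the 23-gene panel; each is analysed with the covariate-
    adjusted score backend.  Returns the pathway rejection rate at alpha=0.05
    and a KS test of the pooled gene-level p-values against uniform.
    """
    panel = panel or default_panel(max_snps_per_gene=5)
    rng = np.random.default_rng(seed)
    pathway_p = np.empty(n_replicates)
    gene_p: list[np.ndarray] = []
    for r in range(n_replicates):
        s = int(rng.integers(2**31 - 10))
        cohort, genotypes = _simulate_study(
            panel, EffectModel(), n_cases, n_controls, s
        )
        res = run_artp(
            genotypes.dosages, cohort, genotypes.snps[["snp", "gene"]],
            mode="main", adjustment=STUDY_ADJUSTMENT,
            B=B, seed=s + 5, backend="score",
        )
        pathway_p[r] = res.pathway_p
        gene_p.append(res.genes["p_artp"].to_numpy())
    pooled = np.concatenate(gene_p)
    ks = stats.kstest(pooled, "uniform")
    return {
        "pathway_rejection_rate": float(np.mean(pathway_p <= 0.05)),
        "gene_p_ks_stat": float(ks.statistic),
        "gene_p_ks_p": float(ks.pvalue),
        "n_replicates": n_replicates,
        "n_snps": panel.n_snps,
        "B": B,
    }


def gxe_recovery(
    n_replicates: int = 100,
    B: int = 199,
    seed: int = 0,
    n_cases: int = 463,
    n_controls: int = 482,
    eaf: float = 0.13,
    or_former: float = 2.8,
    or_current: float = 0.4,
) -> dict:
    """Power and coverage for a smoking x SNP interaction in a 14-SNP gene.

    One SNP (effect-allele frequency ``eaf``) carries stratum odds ratios of
    1.0 / ``or_former`` / ``or_current`` in never / former / current smokers
    (an interaction-only signal: its marginal main effect is near zero).
    Each replicate refits the smoking-stratified models and runs the gene
    GxE ARTP plus the gene main-effect ARTP.

    Returns per-stratum 95% CI coverage of the generating odds ratios, the
    GxE ARTP rejection rate at alpha=0.05, and the main-effect ARTP rejection
    rate (which should stay near nominal).
    """
    gene = "PER3"
    target = f"{gene}_snp001"
    panel = PanelSpec(
        genes=((gene, 14),), ld_rho=0.5, fixed_mafs={target: eaf}
    )
    model = EffectModel(
        interaction_betas={
            (target, "smoking", "former"): float(np.log(or_former)),
            (target, "smoking", "current"): float(np.log(or_current)),
        }
    )
    true_or = {"never": 1.0, "former": or_former, "current": or_current}
    adj = stratum_adjustment()
    rng = np.random.default_rng(seed)
    covered = {lvl: 0 for lvl in true_or}
    counted = {lvl: 0 for lvl in true_or}
    gxe_p = np.empty(n_replicates)
    main_p = np.empty(n_replicates)
    for r in range(n_replicates):
        s = int(rng.integers(2**31 - 10))
        cohort, genotypes = _simulate_study(panel, model, n_cases, n_controls, s)
        strat = stratified_or(
            genotypes.dosages[target], cohort["smoking"], cohort["status"],
            adj, cohort,
        ).set_index("stratum")
        for lvl, t in true_or.items():
            if lvl in strat.index and strat.loc[lvl, "converged"]:
                counted[lvl] += 1
                if strat.loc[lvl, "ci_low"] <= t <= strat.loc[lvl, "ci_high"]:
                    covered[lvl] += 1
        annotation = genotypes.snps[["snp", "gene"]]
        res_gxe = run_artp(
            genotypes.dosages, cohort, annotation, mode="gxe",
            exposure="smoking", adjustment=STUDY_ADJUSTMENT,
            B=B, seed=s + 5, backend="score",
        )
        res_main = run_artp(
            genotypes.dosages, cohort, annotation, mode="main",
            adjustment=STUDY_ADJUSTMENT, B=B, seed=s + 6, backend="score",
        )
        gxe_p[r] = res_gxe.genes["p_artp"].iloc[0]
        main_p[r] = res_main.genes["p_artp"].iloc[0]
    coverage = {
        lvl: covered[lvl] / counted[lvl] if counted[lvl] else np.nan
        for lvl in true_or
    }
    return {
        "coverage": coverage,
        "gxe_rejection_rate": float(np.mean(gxe_p <= 0.05)),
        "main_rejection_rate": float(np.mean(main_p <= 0.05)),
        "n_replicates": n_replicates,
        "B": B,
    }


def single_snp_gene_gap(
    n: int = 300, B: int = 999, seed: int = 0
) -> float:
    """|gene ARTP p - plain empirical permutation p| for a one-SNP gene."""
    panel = PanelSpec(genes=(("G1", 1),), ld_rho=0.0, seed=seed)
    genotypes = simulate_genotypes(panel, n)
    rng = np.random.default_rng(seed + 1)
    cohort = pd.DataFrame(
        {"status": rng.integers(0, 2, size=n)}, index=genotypes.dosages.index
    )
    from .artp import artp_gene, build_permutation_pvalues

    matrix = build_permutation_pvalues(
        genotypes.dosages, cohort, mode="main", adjustment=None,
        B=B, seed=seed + 2, backend="score",
    )
    res = artp_gene(matrix.values, scheme=TruncationScheme(), gene="G1")
    col = matrix.values[:, 0]
    plain = float(np.mean(col <= col[0]))
    return abs(res.p - plain)
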