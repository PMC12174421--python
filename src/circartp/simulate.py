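"""Synthetic case-control cohorts with LD-structured candidate-gene panels.

The generator emulates a frequency-matched case-control study of women
genotyped on a candidate-gene panel: a circadian pathway of 23 genes totalling
570 tag SNPs, roughly 463 cases and 482 controls, and the questionnaire
covariates used for adjustment (age, residence, education, marital status,
BMI, smoking, age at menarche, parity, oral-contraceptive use).

Genotypes follow a latent-Gaussian haplotype model: each individual carries
two independent latent haplotype vectors per gene; within a gene the latent
variables follow an AR(1) correlation (``ld_rho``) across adjacent SNPs and
are independent across genes.  Thresholding each latent variable at the
normal quantile of the allele frequency yields alleles, and the dosage is the
allele sum.  Because the two haplotypes are independent, every SNP is in
Hardy-Weinberg equilibrium by construction at its drawn frequency, while
adjacent-SNP dosage correlation rises monotonically with ``ld_rho``.

Case-control status is generated from a logistic model
``P(case) = expit(intercept + sum(beta_s * dosage_s) + covariate terms +
interaction terms)`` so that refitting the log-additive model downstream
recovers the generating log-odds ratios.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "PanelSpec",
    "EffectModel",
    "GenotypeMatrix",
    "CATEGORY_LEVELS",
    "AGE_BAND_BOUNDS",
    "GENE_PANEL",
    "default_panel",
    "default_scheme",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_outcome",
    "sample_case_control",
    "perfect_ld_pair",
]

# Closed category sets for every questionnaire covariate.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "age_band": (
        "<30", "30-34", "35-39", "40-44", "45-49", "50-54",
        "55-59", "60-64", "65-69", "70-74", ">=75",
    ),
    "residence": ("Ardennes", "Calvados", "Marne", "Other"),
    "marital": ("couple", "single", "divorced", "widowed"),
    "education": ("<=5", "6-9", "10-12", ">12"),
    "smoking": ("never", "former", "current"),
    "menarche": ("<=12", "13", "14", ">=15"),
    "parity": ("0", "1", "2", "3", "4+"),
    "oc_use": ("never", "ever"),
}

AGE_BAND_BOUNDS: dict[str, tuple[float, float]] = {
    "<30": (25.0, 30.0), "30-34": (30.0, 35.0), "35-39": (35.0, 40.0),
    "40-44": (40.0, 45.0), "45-49": (45.0, 50.0), "50-54": (50.0, 55.0),
    "55-59": (55.0, 60.0), "60-64": (60.0, 65.0), "65-69": (65.0, 70.0),
    "70-74": (70.0, 75.0), ">=75": (75.0, 85.0),
}

# Control-arm category counts used as the default sampling frequencies.
_CONTROL_COUNTS: dict[str, dict[str, int]] = {
    "age_band": {
        "<30": 75, "30-34": 68, "35-39": 42, "40-44": 50, "45-49": 46,
        "50-54": 54, "55-59": 48, "60-64": 31, "65-69": 33, "70-74": 20,
        ">=75": 15,
    },
    "residence": {"Ardennes": 69, "Calvados": 137, "Marne": 183, "Other": 93},
    "marital": {"couple": 350, "single": 47, "divorced": 44, "widowed": 41},
    "education": {"<=5": 96, "6-9": 143, "10-12": 88, ">12": 155},
    "smoking": {"never": 266, "former": 100, "current": 115},
    "menarche": {"<=12": 211, "13": 120, "14": 87, ">=15": 62},
    "parity": {"0": 96, "1": 95, "2": 155, "3": 97, "4+": 39},
    "oc_use": {"never": 97, "ever": 384},
}

# Circadian pathway panel: 23 genes, per-gene tag-SNP counts (570 in total),
# with the cytogenetic region labels of the candidate regions.
GENE_PANEL: tuple[tuple[str, int, str], ...] = (
    ("ARNTL", 23, "11p15"), ("BHLHE40", 8, "3p26"), ("BHLHE41", 3, "12p12"),
    ("BTRC", 13, "10q24"), ("CLOCK", 11, "4q12"), ("CRY1", 7, "12q23"),
    ("CRY2", 9, "11p11"), ("CSNK1D", 3, "17q25"), ("CSNK1E", 10, "22q13"),
    ("CUL1", 22, "7q36"), ("FBXL3", 8, "13q22"), ("FBXW11", 8, "5q35"),
    ("NPAS2", 61, "2q11"), ("NR1D1", 7, "17q21"), ("PER1", 5, "17p13"),
    ("PER2", 11, "2q37"), ("PER3", 14, "1p36"), ("RBX1", 2, "22q13"),
    ("RORA", 285, "15q22"), ("RORB", 35, "9q21"), ("RORC", 13, "1q21"),
    ("SKP1", 4, "5q31"), ("TIMELESS", 8, "12q13"),
)

GENE_REGIONS: dict[str, str] = {g: r for g, _, r in GENE_PANEL}


@dataclass(frozen=True)
class PanelSpec:
    """SNP panel layout: genes with SNP counts, allele-frequency range, LD.

    ``ld_rho`` is the AR(1) latent correlation between adjacent SNPs within a
    gene (0 = linkage equilibrium); ``fixed_mafs`` pins the allele frequency
    of named SNPs (ids are ``<gene>_snp<j>`` with 1-based ``j``).
    """

    genes: tuple[tuple[str, int], ...]
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_rho: float = 0.5
    seed: int = 0
    fixed_mafs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("panel needs at least one gene")
        for gene, m in self.genes:
            if m < 1:
                raise ValueError(f"gene {gene!r} needs n_snps >= 1, got {m}")
        low, high = self.maf_range
        if not (0.0 < low <= high < 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high < 0.5, got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for snp, maf in self.fixed_mafs.items():
            if not (0.0 < maf < 0.5):
                raise ValueError(f"fixed maf for {snp!r} out of (0, 0.5): {maf}")

    @property
    def n_snps(self) -> int:
        return sum(m for _, m in self.genes)


@dataclass
class EffectModel:
    """Generative logistic disease model.

    * ``snp_betas``: SNP id -> log-OR per effect-allele dosage unit.
    * ``covariate_betas``: ``(name, level)`` -> log-OR for a categorical
      level, or plain ``name`` -> slope for a continuous covariate.
    * ``interaction_betas``: ``(snp, exposure, level)`` -> extra log-OR per
      dosage unit within that exposure level; ``level=None`` means a
      dosage x continuous-exposure product term.
    """

    intercept: float = 0.0
    snp_betas: dict[str, float] = field(default_factory=dict)
    covariate_betas: dict = field(default_factory=dict)
    interaction_betas: dict[tuple, float] = field(default_factory=dict)

    def _all_betas(self):
        yield self.intercept
        yield from self.snp_betas.values()
        yield from self.covariate_betas.values()
        yield from self.interaction_betas.values()

    def validate(self) -> None:
        for b in self._all_betas():
            if not np.isfinite(b):
                raise ValueError("all effect-model betas must be finite")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages plus the SNP annotation table.

    ``dosages`` is a float DataFrame in {0, 1, 2, NaN}; ``snps`` has columns
    ``snp, gene, chrom, pos, maf`` (one pseudo-chromosome per gene, positions
    spaced 1 kb).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset(self, individual_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[individual_ids], self.snps.copy())


def default_panel(
    max_snps_per_gene: int | None = None,
    maf_range: tuple[float, float] = (0.05, 0.45),
    ld_rho: float = 0.5,
    seed: int = 0,
) -> PanelSpec:
    """The 23-gene circadian panel (570 SNPs), optionally capped per gene.

    ``max_snps_per_gene=5`` gives the 107-SNP desk-scale panel used by the
    calibration studies.
    """
    genes = tuple(
        (g, m if max_snps_per_gene is None else min(m, max_snps_per_gene))
        for g, m, _ in GENE_PANEL
    )
    return PanelSpec(genes=genes, maf_range=maf_range, ld_rho=ld_rho, seed=seed)


def default_scheme() -> dict:
    """Default covariate sampling scheme (control-arm frequencies)."""
    scheme: dict = {}
    for var, counts in _CONTROL_COUNTS.items():
        total = sum(counts.values())
        scheme[var] = {lvl: c / total for lvl, c in counts.items()}
    scheme["bmi"] = {"median": 23.0, "sigma": 0.18}
    return scheme


def _snp_id(gene: str, j: int) -> str:
    return f"{gene}_snp{j + 1:03d}"


def simulate_genotypes(
    panel: PanelSpec, n: int, seed: int | None = None
) -> GenotypeMatrix:
    """Draw ``n`` individuals' dosages under the latent-haplotype LD model.

    Deterministic given the seed (``panel.seed`` unless overridden).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 individuals, got {n}")
    rng = np.random.default_rng(panel.seed if seed is None else seed)
    low, high = panel.maf_range
    rho = panel.ld_rho
    cols: dict[str, np.ndarray] = {}
    rows = []
    for gene, m in panel.genes:
        mafs = rng.uniform(low, high, size=m)
        ids = [_snp_id(gene, j) for j in range(m)]
        for j, sid in enumerate(ids):
            if sid in panel.fixed_mafs:
                mafs[j] = panel.fixed_mafs[sid]
        thresh = norm.ppf(mafs)
        eps = rng.standard_normal(size=(n, 2, m))
        z = np.empty_like(eps)
        z[:, :, 0] = eps[:, :, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, :, j] = rho * z[:, :, j - 1] + scale * eps[:, :, j]
        dosage = (z < thresh).sum(axis=1).astype(float)
        for j, sid in enumerate(ids):
            cols[sid] = dosage[:, j]
            rows.append(
                {"snp": sid, "gene": gene, "chrom": gene,
                 "pos": 1000 * (j + 1), "maf": mafs[j]}
            )
    index = pd.Index([f"ind_{i + 1:05d}" for i in range(n)], name="individual_id")
    dosages = pd.DataFrame(cols, index=index)
    snps = pd.DataFrame(rows, columns=["snp", "gene", "chrom", "pos", "maf"])
    return GenotypeMatrix(dosages=dosages, snps=snps)


def _validate_scheme(scheme: dict) -> None:
    for var, levels in CATEGORY_LEVELS.items():
        if var not in scheme:
            raise ValueError(f"scheme missing covariate {var!r}")
        table = scheme[var]
        unknown = set(table) - set(levels)
        if unknown:
            raise ValueError(f"unknown {var} levels in scheme: {sorted(unknown)}")
        probs = np.array(list(table.values()), dtype=float)
        if (probs < 0).any():
            raise ValueError(f"negative frequency in scheme for {var!r}")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies for {var!r} must sum to 1 (got {probs.sum():.12f})"
            )


def simulate_covariates(
    n: int, scheme: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Sample a covariate table (no case-control status yet).

    Categorical covariates are drawn from the scheme's frequency tables; age
    is drawn by band then uniformly within the band (both the continuous
    ``age`` and the banded ``age_band`` are kept); BMI is log-normal around
    the scheme's median.
    """
    scheme = default_scheme() if scheme is None else scheme
    _validate_scheme(scheme)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for var, levels in CATEGORY_LEVELS.items():
        table = scheme[var]
        lvls = [lvl for lvl in levels if lvl in table]
        probs = np.array([table[lvl] for lvl in lvls], dtype=float)
        out[var] = rng.choice(lvls, size=n, p=probs / probs.sum())
    bounds = np.array([AGE_BAND_BOUNDS[b] for b in out["age_band"]])
    out["age"] = rng.uniform(bounds[:, 0], bounds[:, 1])
    bmi_cfg = scheme.get("bmi", {"median": 23.0, "sigma": 0.18})
    out["bmi"] = np.exp(
        np.log(bmi_cfg["median"]) + bmi_cfg["sigma"] * rng.standard_normal(n)
    )
    index = pd.Index([f"ind_{i + 1:05d}" for i in range(n)], name="individual_id")
    cols = ["age", "age_band", "residence", "education", "marital",
            "bmi", "smoking", "menarche", "parity", "oc_use"]
    return pd.DataFrame({c: out[c] for c in cols}, index=index)


def _linear_predictor(
    genotypes: GenotypeMatrix, covariates: pd.DataFrame, model: EffectModel
) -> np.ndarray:
    model.validate()
    n = len(covariates)
    eta = np.full(n, model.intercept, dtype=float)
    for snp, beta in model.snp_betas.items():
        if snp not in genotypes.dosages.columns:
            raise ValueError(f"effect model references unknown SNP {snp!r}")
        eta += beta * genotypes.dosages[snp].to_numpy()
    for key, beta in model.covariate_betas.items():
        if isinstance(key, tuple):
            name, level = key
            if name not in CATEGORY_LEVELS or level not in CATEGORY_LEVELS[name]:
                raise ValueError(f"effect model references unknown covariate level {key!r}")
            eta += beta * (covariates[name].to_numpy() == level)
        else:
            if key not in covariates.columns:
                raise ValueError(f"effect model references unknown covariate {key!r}")
            eta += beta * covariates[key].to_numpy(dtype=float)
    for (snp, exposure, level), beta in model.interaction_betas.items():
        if snp not in genotypes.dosages.columns:
            raise ValueError(f"interaction references unknown SNP {snp!r}")
        dose = genotypes.dosages[snp].to_numpy()
        if level is None:
            eta += beta * dose * covariates[exposure].to_numpy(dtype=float)
        else:
            if exposure not in CATEGORY_LEVELS or level not in CATEGORY_LEVELS[exposure]:
                raise ValueError(
                    f"interaction references unknown exposure level ({exposure!r}, {level!r})"
                )
            eta += beta * dose * (covariates[exposure].to_numpy() == level)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor (missing dosages or bad betas)")
    return eta


def simulate_outcome(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    model: EffectModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach Bernoulli case-control status under the logistic effect model."""
    model = EffectModel() if model is None else model
    if not genotypes.dosages.index.equals(covariates.index):
        raise ValueError("genotype and covariate tables must share individuals")
    eta = _linear_predictor(genotypes, covariates, model)
    rng = np.random.default_rng(seed)
    out = covariates.copy()
    out["status"] = (rng.random(len(out)) < expit(eta)).astype(int)
    return out


def sample_case_control(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Draw exactly ``n_cases``/``n_controls`` individuals from a population.

    Emulates case-control ascertainment from the simulated source population
    (matching on age/residence is implicit: both arms are drawn from the same
    covariate scheme).
    """
    if "status" in cohort and cohort["status"].isna().any():
        raise ValueError("cohort has missing status")
    rng = np.random.default_rng(seed)
    cases = cohort.index[cohort["status"] == 1]
    controls = cohort.index[cohort["status"] == 0]
    if len(cases) < n_cases:
        raise ValueError(f"requested {n_cases} cases but only {len(cases)} available")
    if len(controls) < n_controls:
        raise ValueError(
            f"requested {n_controls} controls but only {len(controls)} available"
        )
    pick_cases = rng.choice(cases, size=n_cases, replace=False)
    pick_controls = rng.choice(controls, size=n_controls, replace=False)
    keep = cohort.index[cohort.index.isin(set(pick_cases) | set(pick_controls))]
    return cohort.loc[keep], genotypes.subset(keep)


def perfect_ld_pair(
    genotypes: GenotypeMatrix, snp: str, new_id: str | None = None
) -> GenotypeMatrix:
    """Append an exact copy of ``snp`` (r^2 = 1) to exercise LD reporting."""
    if snp not in genotypes.dosages.columns:
        raise KeyError(snp)
    new_id = new_id or f"{snp}_ld"
    dosages = genotypes.dosages.copy()
    dosages[new_id] = dosages[snp]
    row = genotypes.snps.loc[genotypes.snps["snp"] == snp].iloc[0].copy()
    row["snp"] = new_id
    row["pos"] = int(row["pos"]) + 500
    snps = pd.concat(
        [genotypes.snps, pd.DataFrame([row])], ignore_index=True
    )
    return GenotypeMatrix(dosages=dosages, snps=snps)


def scheme_to_config(scheme: dict) -> dict:
    return copy.deepcopy(scheme)
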