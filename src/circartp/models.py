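"""Per-SNP inference: log-additive logistic regression, interaction LRTs,
stratified odds ratios and dosage LD.

Every model is an unconditional logistic regression with the SNP coded as
the effect-allele count (0/1/2), one log-odds ratio per allele, adjusted for
a configurable covariate set.  Interaction with an exposure is tested by the
likelihood-ratio test comparing the adjusted models with and without the
dosage x exposure term(s); association p-values are Wald by default (the
convention matching OR + CI reporting), with the LRT alternative also
reported.

Missing data policy: individuals with a missing dosage or any missing
adjustment covariate are dropped per fit (pairwise across SNPs); the full
and reduced models of every LRT share an identical analysis set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._glm import firth_logistic_fit
from .simulate import CATEGORY_LEVELS

Z975 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    snp_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    p_lrt: float
    n_used: int
    converged: bool
    note: str = ""


@dataclass
class InteractionResult:
    snp_id: str
    exposure_name: str
    lrt_stat: float
    df: int
    p: float
    converged: bool


@dataclass(frozen=True)
class AdjustmentSet:
    """Ordered covariate coding for the regression adjustment.

    Categorical covariates are dummy-coded against their reference level
    (default: first level of the closed category set); continuous covariates
    enter linearly.  ``extra_continuous`` accepts e.g. principal-component
    score columns already present on the cohort table.
    """

    categorical: tuple[str, ...] = (
        "age_band", "residence", "education", "marital",
        "menarche", "parity", "oc_use", "smoking",
    )
    continuous: tuple[str, ...] = ("bmi",)
    references: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        refs = dict(self.references)
        for var, ref in refs.items():
            if var not in CATEGORY_LEVELS or ref not in CATEGORY_LEVELS[var]:
                raise ValueError(f"unknown reference level {ref!r} for {var!r}")

    def reference_for(self, var: str) -> str:
        return dict(self.references).get(var, CATEGORY_LEVELS[var][0])

    def design(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Dummy/continuous design (no intercept); NaN rows mark missing data."""
        cols: dict[str, np.ndarray] = {}
        for var in self.categorical:
            levels = CATEGORY_LEVELS[var]
            vals = cohort[var]
            bad = vals.dropna()[~vals.dropna().isin(levels)]
            if len(bad):
                raise ValueError(
                    f"unknown {var!r} labels: {sorted(bad.unique())}"
                )
            ref = self.reference_for(var)
            miss = vals.isna().to_numpy()
            for lvl in levels:
                if lvl == ref:
                    continue
                col = (vals == lvl).to_numpy(dtype=float)
                col[miss] = np.nan
                cols[f"{var}[{lvl}]"] = col
        for var in self.continuous:
            cols[var] = cohort[var].to_numpy(dtype=float)
        return pd.DataFrame(cols, index=cohort.index)

    def without(self, var: str) -> "AdjustmentSet":
        return AdjustmentSet(
            categorical=tuple(v for v in self.categorical if v != var),
            continuous=tuple(v for v in self.continuous if v != var),
            references=tuple((k, v) for k, v in self.references if k != var),
        )

    def with_exposure(self, exposure: str) -> "AdjustmentSet":
        """Ensure the exposure's main effect is part of the adjustment."""
        if exposure in self.categorical or exposure in self.continuous:
            return self
        if exposure in CATEGORY_LEVELS:
            return AdjustmentSet(
                categorical=self.categorical + (exposure,),
                continuous=self.continuous,
                references=self.references,
            )
        return AdjustmentSet(
            categorical=self.categorical,
            continuous=self.continuous + (exposure,),
            references=self.references,
        )


def default_adjustment() -> AdjustmentSet:
    """Full questionnaire adjustment (matching variables + confounders)."""
    return AdjustmentSet()


def stratum_adjustment() -> AdjustmentSet:
    """Adjustment used for smoking-stratified odds ratios: age (continuous —
    strata are small, so banded age would burn 10 df), residence, BMI,
    menarche, parity and OC use; no education/marital, and never the stratum
    variable itself."""
    return AdjustmentSet(
        categorical=("residence", "menarche", "parity", "oc_use"),
        continuous=("bmi", "age"),
    )


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """statsmodels Logit fit; returns (result-or-None, converged flag)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
        except Exception:
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
            except Exception:
                return None, False
    bse = np.asarray(res.bse)
    converged = bool(res.mle_retvals.get("converged", False))
    converged = converged and np.all(np.isfinite(bse)) and np.abs(res.params).max() < 15
    return res, converged


def _design_matrix(
    dosage: pd.Series,
    status: pd.Series,
    adjustment: AdjustmentSet | None,
    cohort: pd.DataFrame | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Complete-case (y, Z_with_intercept, x, index) for one SNP."""
    parts = pd.DataFrame({"__y": status, "__x": dosage})
    if adjustment is not None:
        if cohort is None:
            raise ValueError("adjustment requires the cohort table")
        parts = parts.join(adjustment.design(cohort), how="left")
    parts = parts.dropna()
    y = parts.pop("__y").to_numpy(dtype=float)
    x = parts.pop("__x").to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(parts))] + [parts[c].to_numpy() for c in parts])
    return y, Z, x, parts.index


def fit_additive(
    dosage: pd.Series,
    status: pd.Series,
    adjustment: AdjustmentSet | None = None,
    cohort: pd.DataFrame | None = None,
    snp_id: str | None = None,
) -> AssociationResult:
    """Log-additive association fit for one SNP.

    Returns a structured result in all degenerate cases: a monomorphic SNP
    yields ``note='monomorphic'``; separation or non-convergence yields
    ``converged=False`` with missing p.
    """
    snp_id = snp_id or (dosage.name if dosage.name else "snp")
    y, Z, x, _ = _design_matrix(dosage, status, adjustment, cohort)
    nan = AssociationResult(
        snp_id, np.nan, np.nan, np.nan, (np.nan, np.nan),
        np.nan, np.nan, len(y), False,
    )
    if len(np.unique(y)) < 2:
        raise ValueError("need both cases and controls in the analysis set")
    if np.ptp(x) == 0:
        nan.note = "monomorphic"
        return nan
    X = np.column_stack([Z, x])
    res, converged = _fit_logit(X, y)
    if res is None:
        nan.note = "fit_failed"
        return nan
    beta = float(res.params[-1])
    se = float(res.bse[-1])
    p_lrt = np.nan
    res0, conv0 = _fit_logit(Z, y)
    if res0 is not None and conv0 and converged:
        stat = max(0.0, 2.0 * (res.llf - res0.llf))
        p_lrt = float(stats.chi2.sf(stat, 1))
    p_wald = float(2 * stats.norm.sf(abs(beta / se))) if converged and se > 0 else np.nan
    with np.errstate(over="ignore"):  # inf CI bounds are fine for separated fits
        or_ = float(np.exp(beta))
        ci = (float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se)))
    return AssociationResult(
        snp_id=snp_id,
        beta=beta,
        se=se,
        or_=or_,
        ci95=ci,
        p=p_wald,
        p_lrt=p_lrt,
        n_used=len(y),
        converged=converged,
        note="" if converged else "separation_or_nonconvergence",
    )


def _exposure_design(
    exposure: pd.Series, name: str, adjustment: AdjustmentSet
) -> tuple[np.ndarray, int, np.ndarray]:
    """(columns to interact with dosage, df, missing mask) for one exposure."""
    if name in CATEGORY_LEVELS:
        levels = CATEGORY_LEVELS[name]
        ref = adjustment.reference_for(name) if name in adjustment.categorical else levels[0]
        miss = exposure.isna().to_numpy()
        cols = []
        for lvl in levels:
            if lvl == ref:
                continue
            col = (exposure == lvl).to_numpy(dtype=float)
            col[miss] = np.nan
            cols.append(col)
        E = np.column_stack(cols)
        return E, E.shape[1], miss
    vals = exposure.to_numpy(dtype=float)
    return vals[:, None], 1, ~np.isfinite(vals)


def interaction_lrt(
    dosage: pd.Series,
    exposure: pd.Series,
    status: pd.Series,
    adjustment: AdjustmentSet | None = None,
    cohort: pd.DataFrame | None = None,
    snp_id: str | None = None,
) -> InteractionResult:
    """Likelihood-ratio test for dosage x exposure interaction.

    Both models contain the SNP and exposure main effects plus the
    adjustment; df equals the number of interaction columns (levels - 1 for a
    categorical exposure, 1 for a continuous one).  Non-convergence of either
    fit propagates a missing p.
    """
    snp_id = snp_id or (dosage.name if dosage.name else "snp")
    name = exposure.name if exposure.name else "exposure"
    observed = exposure.dropna().unique()
    if len(observed) < 2 and name in CATEGORY_LEVELS:
        raise ValueError(f"exposure {name!r} has fewer than 2 observed levels")
    adj = (adjustment or AdjustmentSet()).with_exposure(name)
    if cohort is None:
        cohort = pd.DataFrame({name: exposure})
    elif name not in cohort.columns:
        cohort = cohort.assign(**{name: exposure})
    y, Z, x, idx = _design_matrix(dosage, status, adj, cohort)
    E, df, _ = _exposure_design(exposure.loc[idx], name, adj)
    reduced = np.column_stack([Z, x])
    full = np.column_stack([reduced, x[:, None] * E])
    res_full, conv_full = _fit_logit(full, y)
    res_red, conv_red = _fit_logit(reduced, y)
    if res_full is None or res_red is None or not (conv_full and conv_red):
        return InteractionResult(snp_id, name, np.nan, df, np.nan, False)
    stat = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    return InteractionResult(
        snp_id, name, stat, df, float(stats.chi2.sf(stat, df)), True
    )


def stratified_or(
    dosages: pd.DataFrame | pd.Series,
    stratum: pd.Series,
    status: pd.Series,
    adjustment: AdjustmentSet | None = None,
    cohort: pd.DataFrame | None = None,
    joint: bool = False,
    method: str = "firth",
) -> pd.DataFrame:
    """Per-stratum odds ratios (uni-locus, or multi-loci with ``joint=True``).

    Fits an independent adjusted model within each stratum level; the joint
    variant enters all SNPs together (rank deficiency among the SNP columns
    is detected and reported rather than fitted through).  Strata lacking
    cases or controls are skipped with a warning.

    ``method="firth"`` (default) uses Firth bias-reduced logistic regression
    — strata are small and effect alleles can be rare, where the plain MLE
    is biased away from the null and may not even be finite; ``method="mle"``
    gives the ordinary fit.
    """
    if isinstance(dosages, pd.Series):
        dosages = dosages.to_frame()
    name = stratum.name or "stratum"
    adj = (adjustment or stratum_adjustment()).without(name)
    rows = []
    levels = CATEGORY_LEVELS.get(name, tuple(pd.unique(stratum.dropna())))
    for lvl in levels:
        mask = (stratum == lvl).to_numpy()
        if mask.sum() == 0 or status[mask].nunique() < 2:
            warnings.warn(f"stratum {name}={lvl!r} lacks both outcome classes; skipped")
            continue
        sub_cohort = cohort.loc[mask] if cohort is not None else None
        sub_status = status[mask]
        if joint:
            sub = dosages.loc[mask]
            parts = pd.DataFrame({"__y": sub_status}).join(
                sub, how="left"
            )
            if adj.categorical or adj.continuous:
                parts = parts.join(adj.design(sub_cohort), how="left")
            parts = parts.dropna()
            y = parts.pop("__y").to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(parts))] + [parts[c].to_numpy() for c in parts])
            snp_cols = {s: 1 + list(parts.columns).index(s) for s in sub.columns}
            rank_ok = np.linalg.matrix_rank(X) == X.shape[1]
            if not rank_ok:
                for snp in sub.columns:
                    rows.append({"stratum": lvl, "snp": snp, "model": "multi",
                                 "beta": np.nan, "se": np.nan, "or": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                                 "n_used": len(y), "converged": False,
                                 "note": "rank_deficient"})
                continue
            if method == "firth":
                fit = firth_logistic_fit(X, y)
                ok = fit.converged and fit.cov is not None
                for snp, j in snp_cols.items():
                    se = float(np.sqrt(fit.cov[j, j])) if ok else np.nan
                    rows.append(_or_row(lvl, snp, "multi", float(fit.beta[j]),
                                        se, len(y), ok))
            else:
                res, converged = _fit_logit(X, y)
                for snp, j in snp_cols.items():
                    if res is None:
                        beta = se = np.nan
                    else:
                        beta, se = float(res.params[j]), float(res.bse[j])
                    rows.append(_or_row(lvl, snp, "multi", beta, se, len(y),
                                        converged))
        else:
            for snp in dosages.columns:
                if method == "firth":
                    y, Z, x, _ = _design_matrix(
                        dosages[snp].loc[mask], sub_status, adj, sub_cohort
                    )
                    if np.ptp(x) == 0:
                        rows.append(_or_row(lvl, snp, "uni", np.nan, np.nan,
                                            len(y), False))
                        continue
                    fit = firth_logistic_fit(np.column_stack([Z, x]), y)
                    ok = fit.converged and fit.cov is not None
                    se = float(np.sqrt(fit.cov[-1, -1])) if ok else np.nan
                    rows.append(_or_row(lvl, snp, "uni", float(fit.beta[-1]),
                                        se, len(y), ok))
                else:
                    r = fit_additive(
                        dosages[snp].loc[mask], sub_status, adj, sub_cohort,
                        snp_id=snp,
                    )
                    rows.append({"stratum": lvl, "snp": snp, "model": "uni",
                                 "beta": r.beta, "se": r.se, "or": r.or_,
                                 "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                                 "p": r.p, "n_used": r.n_used,
                                 "converged": r.converged, "note": r.note})
    return pd.DataFrame(rows)


def _or_row(lvl, snp, model, beta, se, n, converged):
    return {
        "stratum": lvl, "snp": snp, "model": model, "beta": beta, "se": se,
        "or": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
        "ci_low": float(np.exp(beta - Z975 * se)) if np.isfinite(se) else np.nan,
        "ci_high": float(np.exp(beta + Z975 * se)) if np.isfinite(se) else np.nan,
        "p": float(2 * stats.norm.sf(abs(beta / se)))
        if converged and np.isfinite(se) and se > 0 else np.nan,
        "n_used": n, "converged": converged, "note": "" if converged else "nonconvergence",
    }


def ld_r2(a: pd.Series, b: pd.Series) -> float:
    """Squared Pearson correlation of dosages on shared non-missing rows.

    Undefined (NaN) when either SNP is constant on the shared rows; invariant
    to allele relabeling (dosage -> 2 - dosage).
    """
    df = pd.DataFrame({"a": a, "b": b}).dropna()
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        return np.nan
    r = np.corrcoef(df["a"], df["b"])[0, 1]
    r2 = float(r * r)
    # snap float noise so perfect LD is reported as exactly 1 (the pruning
    # rule for duplicated tag SNPs keys on r^2 == 1)
    return 1.0 if r2 > 1.0 - 1e-12 else r2


def association_scan(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    adjustment: AdjustmentSet | None = None,
) -> pd.DataFrame:
    """fit_additive across every SNP column; one tidy row per SNP."""
    status = cohort["status"]
    rows = []
    for snp in dosages.columns:
        r = fit_additive(dosages[snp], status, adjustment, cohort, snp_id=snp)
        rows.append({
            "snp": r.snp_id, "beta": r.beta, "se": r.se, "or": r.or_,
            "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p,
            "p_lrt": r.p_lrt, "n_used": r.n_used, "converged": r.converged,
            "note": r.note,
        })
    return pd.DataFrame(rows)


def interaction_scan(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    exposure: str,
    adjustment: AdjustmentSet | None = None,
) -> pd.DataFrame:
    """interaction_lrt across every SNP column for one exposure."""
    status = cohort["status"]
    rows = []
    for snp in dosages.columns:
        r = interaction_lrt(
            dosages[snp], cohort[exposure], status, adjustment, cohort, snp_id=snp
        )
        rows.append({
            "snp": r.snp_id, "exposure": r.exposure_name, "lrt_stat": r.lrt_stat,
            "df": r.df, "p": r.p, "converged": r.converged,
        })
    return pd.DataFrame(rows)
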