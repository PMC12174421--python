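"""End-to-end orchestration: QC -> SNP scan -> ARTP -> GxE -> stratified ORs.

``run_full_analysis`` wires the stages together, applies Benjamini-Hochberg
correction within the families the study design implies (all SNPs for the
association scan; the genes for gene-level ARTP; each exposure's scan
separately), and writes one tidy TSV per report table plus a YAML metadata
sidecar recording seeds, permutation counts and convergence-failure counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .artp import TruncationScheme, run_artp
from .fdr import fdr_adjust
from .models import (
    AdjustmentSet,
    association_scan,
    default_adjustment,
    interaction_scan,
    stratified_or,
    stratum_adjustment,
)
from .qc import QcResult, QcThresholds, run_qc
from .simulate import CATEGORY_LEVELS

logger = logging.getLogger("circartp")

DEFAULT_EXPOSURES = ("bmi", "smoking", "menarche", "parity", "oc_use")


@dataclass
class RunConfig:
    outdir: str | Path | None = None
    genotypes_tsv: str | None = None
    genotypes_vcf: str | None = None
    covariates_tsv: str | None = None
    annotation_bed: str | None = None
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    adjustment: AdjustmentSet = field(default_factory=default_adjustment)
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES
    scheme: TruncationScheme = field(default_factory=TruncationScheme)
    B: int = 199
    seed: int = 17
    backend: str = "refit"
    gxe_q_threshold: float = 0.05
    use_pcs: bool = False
    prune_perfect_ld: bool = False

    def validate(self) -> None:
        unknown = [e for e in self.exposures
                   if e not in CATEGORY_LEVELS and e != "bmi"]
        if unknown:
            raise ValueError(f"unknown exposures: {unknown}")
        for path in (self.genotypes_tsv, self.genotypes_vcf,
                     self.covariates_tsv, self.annotation_bed):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _load_inputs(config: RunConfig):
    if config.genotypes_vcf:
        genotypes = cio.read_vcf(config.genotypes_vcf)
    elif config.genotypes_tsv:
        genotypes = cio.read_dosage_tsv(config.genotypes_tsv)
    else:
        raise ValueError("config names no genotype input")
    cohort = cio.read_covariates_tsv(config.covariates_tsv)
    if config.annotation_bed:
        windows = cio.read_bed(config.annotation_bed)
        annotation = cio.map_snps_to_genes(genotypes.snps, windows)
    else:
        annotation = genotypes.snps[["snp", "gene"]].dropna()
    return genotypes, cohort, annotation


def _prune_perfect_ld(dosages: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop the later member of each exactly-duplicated dosage column pair."""
    dropped = []
    seen: dict[bytes, str] = {}
    for snp in dosages.columns:
        key = dosages[snp].to_numpy().tobytes()
        if key in seen:
            dropped.append(snp)
        else:
            seen[key] = snp
    return dosages.drop(columns=dropped), dropped


def run_full_analysis(
    config: RunConfig,
    genotypes=None,
    cohort: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage; returns the report bundle as a dict of tables.

    Data can be passed in memory (``genotypes``/``cohort``/``annotation``)
    or read from the paths in the config.  Any stage failure aborts with a
    stage-named error; tables written so far stay on disk.
    """
    config.validate()
    if genotypes is None or cohort is None:
        genotypes, cohort, annotation = _load_inputs(config)
    if annotation is None:
        annotation = genotypes.snps[["snp", "gene"]].dropna()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def _emit(name: str, table: pd.DataFrame):
        bundle[name] = table
        if outdir is not None:
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("qc")
        qc: QcResult = run_qc(genotypes.dosages, cohort, config.thresholds)
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc
    _emit("qc_snps", qc.snp_report.to_frame())
    _emit("qc_samples", qc.sample_report.to_frame())
    dosages, cohort = qc.dosages, qc.cohort
    if config.prune_perfect_ld:
        dosages, dropped = _prune_perfect_ld(dosages)
        if dropped:
            logger.info("pruned %d perfect-LD duplicates", len(dropped))
    adjustment = config.adjustment
    if config.use_pcs and len(qc.pc_scores.columns):
        pc_cols = list(qc.pc_scores.columns)
        cohort = cohort.join(qc.pc_scores)
        adjustment = replace(
            adjustment, continuous=adjustment.continuous + tuple(pc_cols)
        )
    annotation = annotation[annotation["snp"].isin(dosages.columns)]

    try:
        _stage("association_scan")
        assoc = association_scan(dosages, cohort, adjustment)
    except Exception as exc:
        raise RuntimeError(f"stage association_scan failed: {exc}") from exc
    ok = assoc["p"].notna()
    assoc["q_fdr"] = pd.NA
    if ok.any():
        assoc.loc[ok, "q_fdr"] = fdr_adjust(assoc.loc[ok, "p"]).qvalues
    info = genotypes.snps.set_index("snp")
    assoc.insert(1, "gene", assoc["snp"].map(info["gene"]))
    assoc.insert(2, "eaf", assoc["snp"].map(info["maf"]))
    _emit("snp_associations", assoc)

    try:
        _stage("artp_main")
        artp_main = run_artp(
            dosages, cohort, annotation, mode="main",
            adjustment=adjustment, scheme=config.scheme,
            B=config.B, seed=config.seed, backend=config.backend,
        )
    except Exception as exc:
        raise RuntimeError(f"stage artp_main failed: {exc}") from exc
    gene_table = artp_main.genes.copy()
    gene_table["q_fdr"] = fdr_adjust(gene_table["p_artp"]).qvalues
    gene_table["pathway_p"] = artp_main.pathway_p
    _emit("artp_main", gene_table)

    gxe_gene_tables = []
    gxe_snp_tables = []
    strat_tables = []
    for k, exposure in enumerate(config.exposures):
        try:
            _stage(f"gxe_{exposure}")
            scan = interaction_scan(dosages, cohort, exposure, adjustment)
            ok = scan["p"].notna()
            scan["q_fdr"] = pd.NA
            if ok.any():
                scan.loc[ok, "q_fdr"] = fdr_adjust(scan.loc[ok, "p"]).qvalues
            gxe_snp_tables.append(scan)
            artp_gxe = run_artp(
                dosages, cohort, annotation, mode="gxe", exposure=exposure,
                adjustment=adjustment, scheme=config.scheme,
                B=config.B, seed=config.seed + 1 + k, backend=config.backend,
            )
            gt = artp_gxe.genes.rename(
                columns={"p_artp": f"p_{exposure}", "best_k": f"best_k_{exposure}"}
            )
            gt[f"q_{exposure}"] = fdr_adjust(gt[f"p_{exposure}"]).qvalues
            gt[f"pathway_p_{exposure}"] = artp_gxe.pathway_p
            gxe_gene_tables.append(gt.set_index(["gene", "n_snps"]))
        except Exception as exc:
            raise RuntimeError(f"stage gxe_{exposure} failed: {exc}") from exc
        hits = scan.loc[
            scan["q_fdr"].notna() & (scan["q_fdr"] <= config.gxe_q_threshold), "snp"
        ]
        if len(hits) and exposure in CATEGORY_LEVELS:
            _stage(f"stratified_or_{exposure}")
            strat = stratified_or(
                dosages[list(hits)], cohort[exposure], cohort["status"],
                stratum_adjustment().without(exposure), cohort,
            )
            strat.insert(0, "exposure", exposure)
            strat_tables.append(strat)
    if gxe_snp_tables:
        _emit("gxe_snp_scan", pd.concat(gxe_snp_tables, ignore_index=True))
    if gxe_gene_tables:
        _emit("artp_gxe", pd.concat(gxe_gene_tables, axis=1).reset_index())
    _emit(
        "stratified_or",
        pd.concat(strat_tables, ignore_index=True) if strat_tables
        else pd.DataFrame(columns=["exposure", "stratum", "snp", "model", "beta",
                                   "se", "or", "ci_low", "ci_high", "p",
                                   "n_used", "converged", "note"]),
    )
    metadata = {
        "B": config.B,
        "seed": config.seed,
        "backend": config.backend,
        "truncation": {
            "fraction": config.scheme.fraction,
            "n_points_gene": config.scheme.n_points_gene,
            "n_points_pathway": config.scheme.n_points_pathway,
        },
        "exposures": list(config.exposures),
        "n_individuals": int(len(cohort)),
        "n_snps": int(dosages.shape[1]),
        "artp_main_failed_fits": int(artp_main.n_failed),
    }
    bundle["metadata"] = metadata
    if outdir is not None:
        (outdir / "run_metadata.yaml").write_text(yaml.safe_dump(metadata))
    return bundle
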