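"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as VCF (one pseudo-chromosome per gene, GT fields) or as a
TSV dosage matrix (individuals x SNPs, values 0/1/2 or blank for missing);
covariates/outcome as a headered TSV; the panel annotation as BED (0-based,
half-open gene windows) plus a SNP table; scenarios as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import EffectModel, GenotypeMatrix, PanelSpec

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Plain-text VCF 4.2 with GT fields; effect allele is the ALT allele."""
    snps = genotypes.snps
    dosages = genotypes.dosages
    lines = ["##fileformat=VCFv4.2", "##source=circartp"]
    for chrom, sub in snps.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = list(dosages.index)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for _, row in snps.iterrows():
        doses = dosages[row["snp"]].to_numpy()
        gts = "\t".join(_GT.get(d, "./.") for d in doses)
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\tA\tG\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT dosages from an (uncompressed or bgzipped) VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    cols, rows = {}, []
    for variant in vcf:
        doses = np.array(
            [a + b if a >= 0 and b >= 0 else np.nan
             for a, b, *_ in variant.genotypes],
            dtype=float,
        )
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        cols[sid] = doses
        rows.append({"snp": sid, "gene": variant.CHROM, "chrom": variant.CHROM,
                     "pos": variant.POS, "maf": np.nan})
    index = pd.Index(samples, name="individual_id")
    return GenotypeMatrix(
        dosages=pd.DataFrame(cols, index=index),
        snps=pd.DataFrame(rows, columns=["snp", "gene", "chrom", "pos", "maf"]),
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.dosages.to_csv(path, sep="\t", na_rep="")


def read_dosage_tsv(path, snps: pd.DataFrame | None = None) -> GenotypeMatrix:
    dosages = pd.read_csv(path, sep="\t", index_col=0)
    dosages.index.name = "individual_id"
    if snps is None:
        snps = pd.DataFrame(
            {"snp": dosages.columns, "gene": pd.NA, "chrom": pd.NA,
             "pos": pd.NA, "maf": np.nan}
        )
    return GenotypeMatrix(dosages=dosages.astype(float), snps=snps)


def write_covariates_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", na_rep="")


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in ("age", "bmi"):
        if col in df:
            df[col] = pd.to_numeric(df[col])
    if "status" in df:
        df["status"] = pd.to_numeric(df["status"]).astype("Int64")
    return df


def gene_windows(genotypes: GenotypeMatrix, flank: int = 50_000) -> pd.DataFrame:
    """Per-gene windows (coordinates +/- flank) as 0-based half-open intervals."""
    rows = []
    for gene, sub in genotypes.snps.groupby("gene", sort=True):
        lo = max(0, int(sub["pos"].min()) - flank)
        hi = int(sub["pos"].max()) + flank
        rows.append({"chrom": sub["chrom"].iloc[0], "start": lo, "end": hi,
                     "gene": gene})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_bed(windows: pd.DataFrame, path) -> None:
    windows[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
    )


def map_snps_to_genes(snps: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """SNP -> gene annotation by window overlap (a SNP may map to several genes)."""
    merged = snps.merge(windows, on="chrom", suffixes=("", "_w"))
    hit = merged[(merged["pos"] >= merged["start"]) & (merged["pos"] < merged["end"])]
    return hit[["snp", "gene_w"]].rename(columns={"gene_w": "gene"}).drop_duplicates()


# ---------------------------------------------------------------------------
# Scenario configs


def save_scenario(path, panel: PanelSpec, model: EffectModel, n: int,
                  seed: int, scheme: dict | None = None) -> None:
    doc = {
        "panel": {
            "genes": [[g, int(m)] for g, m in panel.genes],
            "maf_range": list(panel.maf_range),
            "ld_rho": panel.ld_rho,
            "seed": panel.seed,
            "fixed_mafs": dict(panel.fixed_mafs),
        },
        "model": {
            "intercept": model.intercept,
            "snp_betas": dict(model.snp_betas),
            "covariate_betas": {
                "|".join(k) if isinstance(k, tuple) else k: v
                for k, v in model.covariate_betas.items()
            },
            "interaction_betas": {
                "|".join("" if x is None else str(x) for x in k): v
                for k, v in model.interaction_betas.items()
            },
        },
        "n": int(n),
        "seed": int(seed),
    }
    if scheme is not None:
        doc["scheme"] = scheme
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    panel = PanelSpec(
        genes=tuple((g, int(m)) for g, m in doc["panel"]["genes"]),
        maf_range=tuple(doc["panel"].get("maf_range", (0.05, 0.45))),
        ld_rho=doc["panel"].get("ld_rho", 0.5),
        seed=doc["panel"].get("seed", 0),
        fixed_mafs=doc["panel"].get("fixed_mafs", {}),
    )
    mdoc = doc.get("model", {})
    covariate_betas = {}
    for k, v in mdoc.get("covariate_betas", {}).items():
        parts = k.split("|")
        covariate_betas[tuple(parts) if len(parts) > 1 else k] = v
    interaction_betas = {}
    for k, v in mdoc.get("interaction_betas", {}).items():
        snp, exposure, level = k.split("|")
        interaction_betas[(snp, exposure, level or None)] = v
    model = EffectModel(
        intercept=mdoc.get("intercept", 0.0),
        snp_betas=mdoc.get("snp_betas", {}),
        covariate_betas=covariate_betas,
        interaction_betas=interaction_betas,
    )
    return {
        "panel": panel,
        "model": model,
        "n": int(doc["n"]),
        "seed": int(doc.get("seed", 0)),
        "scheme": doc.get("scheme"),
    }
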