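"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCFv4.2 (GT field only; read through cyvcf2)
or as a dosage TSV (variants x samples with a metadata block). All other
tables — methylation, proportions, covariates, reference panels, summary
statistics — are plain TSV with documented headers; paths ending in
``.gz`` are compressed transparently by pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MethylationMatrix, ReferencePanel

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal VCFv4.2 with GT only."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(gm.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    samples = "\t".join(gm.samples)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}")
    dos = gm.dosages.to_numpy(float)
    for v, (vid, row) in enumerate(gm.variants.iterrows()):
        gts = "\t".join(
            _GT_CODES.get(d, "./.") if np.isfinite(d) else "./." for d in dos[:, v]
        )
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix via cyvcf2 (alt-allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, meta, rows = [], [], []
    for var in vcf:
        vid = var.ID or f"chr{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
        ids.append(vid)
        meta.append(
            {"chrom": str(var.CHROM), "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]}
        )
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # unknown
        rows.append(gt)
    variants = pd.DataFrame(meta, index=pd.Index(ids, name="variant_id"))
    dosages = pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="sample_id"), columns=variants.index
    )
    return GenotypeMatrix(dosages, variants)


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Dosage TSV: variant metadata columns then one column per sample."""
    out = gm.variants[["chrom", "pos", "ref", "alt"]].copy()
    out = pd.concat([out, gm.dosages.T], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    dosages = df.drop(columns=meta_cols).T
    dosages.index.name = "sample_id"
    return GenotypeMatrix(dosages.astype(float), variants)


def write_methylation_tsv(mm: MethylationMatrix, path) -> None:
    """Methylation TSV: rows are CpGs; chrom/pos columns then samples."""
    out = pd.concat([mm.positions[["chrom", "pos"]], mm.values], axis=1)
    out.to_csv(path, sep="\t", index_label="cpg_id")


def read_methylation_tsv(path, scale: str = "beta") -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cpg_id")
    positions = df[["chrom", "pos"]].copy()
    positions["chrom"] = positions["chrom"].astype(str)
    values = df.drop(columns=["chrom", "pos"]).astype(float)
    return MethylationMatrix(values, positions, scale=scale)


def write_proportions_tsv(props: pd.DataFrame, path) -> None:
    props.to_csv(path, sep="\t", index_label="sample_id")


def read_proportions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_covariates_tsv(covars: pd.DataFrame, path) -> None:
    covars.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_panel_tsv(panel: ReferencePanel, path) -> None:
    """Panel TSV: cpg_id, one column per cell type, target_type, delta, fdr."""
    out = panel.centroid.copy()
    if len(panel.provenance):
        out = pd.concat([out, panel.provenance[["target_type", "delta", "fdr"]]], axis=1)
    out.to_csv(path, sep="\t", index_label="cpg_id")


def read_panel_tsv(path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", index_col="cpg_id")
    prov_cols = [c for c in ("target_type", "delta", "fdr") if c in df.columns]
    centroid = df.drop(columns=prov_cols)
    provenance = df[prov_cols] if prov_cols else pd.DataFrame(index=df.index)
    return ReferencePanel(centroid=centroid, provenance=provenance)


def read_summary_stats_tsv(path) -> pd.DataFrame:
    """Summary-statistic track: variant_id, chrom, pos, ref, alt and either
    beta/se or p/maf/n (SEs then reconstructed for ABF use)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"summary stats need columns {sorted(required)}")
    df["chrom"] = df["chrom"].astype(str)
    if {"beta", "se"} <= set(df.columns):
        return df
    if {"p", "maf", "n"} <= set(df.columns):
        from .coloc import se_from_pvalue

        effect, se = se_from_pvalue(df["p"], df["maf"], df["n"])
        df["beta"], df["se"] = effect, se
        return df
    raise ValueError("summary stats need beta/se or p/maf/n columns")
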