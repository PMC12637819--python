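"""Core in-memory containers shared across the pipeline.

Conventions:

* Genotype dosages are samples x variants, values in {0, 1, 2} (alt-allele
  count) or NaN for missing.
* Methylation matrices are CpG x sample, beta scale in (0, 1) unless a
  transform is documented.
* Positions are 1-based (VCF convention); BED intervals are 0-based
  half-open and converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    Attributes
    ----------
    dosages : DataFrame, shape (n_samples, n_variants)
        Alt-allele dosage in {0, 1, 2}; NaN marks missing calls.
    variants : DataFrame indexed by variant id
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns must match variant index")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant (ignoring missing calls)."""
        p = self.dosages.mean(axis=0) / 2.0
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1).rename("maf")

    def subset_variants(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosages.loc[:, ids], self.variants.loc[ids])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[ids], self.variants)


@dataclass
class MethylationMatrix:
    """CpG x sample methylation values with CpG genomic positions.

    ``values`` may be on the beta scale or transformed (M-value / INT);
    ``scale`` records which.
    """

    values: pd.DataFrame
    positions: pd.DataFrame  # index cpg_id; columns chrom, pos (1-based)
    scale: str = "beta"

    def __post_init__(self) -> None:
        if not self.positions.index.equals(self.values.index):
            self.positions = self.positions.loc[self.values.index]

    @property
    def cpgs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ReferencePanel:
    """DMC x cell-type centroid used for reference-based deconvolution.

    ``centroid`` holds mean beta values per differentially methylated
    cytosine (row) and cell type (column); ``provenance`` records, per DMC,
    the target cell type it discriminates, the observed hypomethylation
    difference (target minus rest, negative) and the selection FDR.
    """

    centroid: pd.DataFrame
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.centroid.columns.duplicated().any():
            raise ValueError("panel cell-type columns must be unique")
        vals = self.centroid.to_numpy(float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("centroid values must lie in [0, 1]")
        if len(self.provenance) and self.provenance["target_type"].isna().any():
            raise ValueError("every DMC needs exactly one target cell type")

    @property
    def cell_types(self) -> list[str]:
        return list(self.centroid.columns)

    @property
    def dmcs(self) -> pd.Index:
        return self.centroid.index
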