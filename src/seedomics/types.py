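"""Core in-memory containers shared across the analysis modules.

Genotypes are held as an accessions x variants dosage matrix (counts of the
alternate allele, 0/1/2) with ``numpy.nan`` marking missing calls.  Variant
and accession metadata travel alongside as pandas DataFrames, mirroring how
VCF-backed tools keep site and sample annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix with site/sample metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_accessions, n_variants)
        Alternate-allele dosage in {0, 1, 2}; ``nan`` = missing.
    variants : DataFrame
        One row per variant with at least columns
        ``id, chrom, pos, ref, alt`` (``pos`` is 1-based).
    accessions : DataFrame
        One row per accession with at least an ``id`` column and an
        optional ``subpop`` label.
    haplotypes : ndarray, optional
        Phased 0/1 haplotype matrix of shape (2 * n_accessions, n_variants)
        when the source provides phase (the synthetic generator does);
        consecutive row pairs belong to one accession.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    accessions: pd.DataFrame
    haplotypes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x variants)")
        n_acc, n_var = self.dosages.shape
        if len(self.variants) != n_var:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {n_var} columns"
            )
        if len(self.accessions) != n_acc:
            raise ValueError(
                f"accession table has {len(self.accessions)} rows for {n_acc} rows"
            )
        self.variants = self.variants.reset_index(drop=True)
        self.accessions = self.accessions.reset_index(drop=True)
        # positions must be sorted within each chromosome
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError("variant positions must be sorted within chromosome")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx) -> "GenotypeMatrix":
        """Subset by variant (column) indices, keeping metadata aligned."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            accessions=self.accessions.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def take_accessions(self, idx) -> "GenotypeMatrix":
        """Subset by accession (row) indices."""
        idx = np.asarray(idx)
        hap = None
        if self.haplotypes is not None:
            hrows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            hap = self.haplotypes[hrows]
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variants=self.variants.copy(),
            accessions=self.accessions.iloc[idx].reset_index(drop=True),
            haplotypes=hap,
        )

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())


@dataclass
class ExpressionMatrix:
    """Genes x accessions expression matrix (TPM scale) with gene coordinates.

    ``genes`` requires columns ``gene_id, chrom, start, end, strand``; the TSS
    is the ``start`` on '+' strand genes and ``end`` on '-' strand genes.
    """

    tpm: pd.DataFrame  # index = gene_id, columns = accession ids
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.set_index("gene_id", drop=False) if (
            self.genes.index.name != "gene_id"
        ) else self.genes
        if not self.tpm.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = self.tpm.index.difference(self.genes.index)
        if len(missing):
            raise ValueError(f"{len(missing)} expressed genes lack coordinates")

    @property
    def tss(self) -> pd.Series:
        g = self.genes.loc[self.tpm.index]
        return g["start"].where(g["strand"] == "+", g["end"])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(tpm=self.tpm.loc[gene_ids], genes=self.genes)


@dataclass
class PhenotypeTable:
    """Long-format phenotype table plus per-accession BLUE values.

    ``records`` columns: accession_id, trait, year, value.
    ``blue`` : DataFrame indexed by accession_id, one column per trait.
    """

    records: pd.DataFrame
    blue: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.blue is None:
            # two-year (or multi-year) mean fallback when no BLUE supplied
            wide = self.records.pivot_table(
                index="accession_id", columns="trait", values="value", aggfunc="mean"
            )
            wide.columns.name = None
            self.blue = wide

    def trait_values(self, trait: str, accession_ids) -> np.ndarray:
        return self.blue.loc[list(accession_ids), trait].to_numpy(dtype=float)
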