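"""Readers for the study's on-disk formats.

VCF handling lives in :mod:`seedomics.genotypes`; here are the flat-file
companions: expression TSV (genes x accessions, TPM), long phenotype TSV
with BLUE column, GFF3 gene models (1-based inclusive) and BED intervals
(0-based half-open, kept in BED convention in memory).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .types import ExpressionMatrix, PhenotypeTable

__all__ = [
    "read_gff3_genes",
    "read_expression_tsv",
    "read_phenotypes_tsv",
    "read_bed",
]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file: gene_id, chrom, start, end, strand."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ValueError(f"{path}: gene feature without ID: {line.strip()}")
            rows.append((gid, parts[0], int(parts[3]), int(parts[4]), parts[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_expression_tsv(path, gff3_path=None, genes: Optional[pd.DataFrame] = None) -> ExpressionMatrix:
    """Expression TSV (first column gene ids, remaining columns accessions)
    joined with gene coordinates from a GFF3 or a preloaded gene table."""
    tpm = pd.read_csv(path, sep="\t", index_col=0)
    if genes is None:
        if gff3_path is None:
            raise ValueError("provide gff3_path or a gene table")
        genes = read_gff3_genes(gff3_path)
    return ExpressionMatrix(tpm=tpm, genes=genes)


def read_phenotypes_tsv(path) -> PhenotypeTable:
    """Phenotype TSV with columns accession_id, trait, year, value[, blue]."""
    rec = pd.read_csv(path, sep="\t")
    blue = None
    if "blue" in rec.columns:
        blue = (
            rec.drop_duplicates(["accession_id", "trait"])
            .pivot(index="accession_id", columns="trait", values="blue")
        )
        blue.columns.name = None
    return PhenotypeTable(records=rec[["accession_id", "trait", "year", "value"]], blue=blue)


def read_bed(path) -> pd.DataFrame:
    """BED intervals as chrom/start/end (0-based half-open, unchanged)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    if (bed["end"] <= bed["start"]).any():
        raise ValueError(f"{path}: malformed interval with end <= start")
    return bed
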