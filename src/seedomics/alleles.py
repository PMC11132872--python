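"""Superior-allele bookkeeping and genetic-architecture summaries.

A candidate gene's superior allele at its lead GWAS variant is the allele
whose dosage increases the trait (by the sign of the estimated effect).
Aggregation across candidates is tested by comparing superior-allele counts
between the top-k and bottom-k accessions ranked by trait value (Wilcoxon
rank-sum).  The MAF-versus-effect profile orients significant effects to
the minor allele and summarises the architecture by the rank correlation of
MAF with effect magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SuperiorAllele",
    "define_superior_alleles",
    "aggregate_and_test",
    "maf_effect_profile",
]


@dataclass
class SuperiorAllele:
    gene: str
    trait: str
    variant: str
    variant_idx: int
    superior: str  # "ref" | "alt"


def define_superior_alleles(
    candidates: pd.DataFrame,
    gwas_results: Dict[str, pd.DataFrame],
    g: GenotypeMatrix,
) -> List[SuperiorAllele]:
    """Superior allele per (candidate gene, trait).

    ``candidates`` needs columns ``trait, gene, lead_gwas_snp``;
    ``gwas_results`` maps trait -> association table.  Positive effect of
    the alternate-allele dosage makes ALT superior, negative makes REF
    superior; candidates whose lead variant is absent from the results are
    skipped.
    """
    id_to_idx = {vid: i for i, vid in enumerate(g.variants["id"])}
    out: List[SuperiorAllele] = []
    for _, row in candidates.iterrows():
        res = gwas_results.get(row["trait"])
        if res is None:
            continue
        hit = res[res["id"] == row["lead_gwas_snp"]]
        if len(hit) == 0 or not np.isfinite(hit["beta"].iloc[0]):
            continue
        if row["lead_gwas_snp"] not in id_to_idx:
            continue
        beta = float(hit["beta"].iloc[0])
        out.append(
            SuperiorAllele(
                gene=str(row["gene"]),
                trait=str(row["trait"]),
                variant=str(row["lead_gwas_snp"]),
                variant_idx=id_to_idx[row["lead_gwas_snp"]],
                superior="alt" if beta > 0 else "ref",
            )
        )
    return out


def superior_allele_counts(
    sas: Sequence[SuperiorAllele], g: GenotypeMatrix, trait: Optional[str] = None
) -> np.ndarray:
    """Per-accession superior-allele dosage summed over candidate loci."""
    total = np.zeros(g.n_accessions)
    for sa in sas:
        if trait is not None and sa.trait != trait:
            continue
        d = g.dosages[:, sa.variant_idx]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        total += d if sa.superior == "alt" else (2.0 - d)
    return total


def aggregate_and_test(
    sas: Sequence[SuperiorAllele],
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    k: int = 50,
) -> Tuple[np.ndarray, float]:
    """Superior-allele counts per accession plus the two-sided Wilcoxon
    rank-sum p between the top-k and bottom-k accessions by trait BLUE.

    Accessions at the k-th rank tie-break deterministically by id.
    """
    if 2 * k > g.n_accessions:
        raise ValueError("2k exceeds the number of accessions")
    counts = superior_allele_counts(sas, g, trait=trait)
    ids = g.accessions["id"].to_numpy()
    y = pheno.blue.loc[ids, trait].to_numpy(dtype=float)
    order = np.lexsort((ids, -y))  # descending trait, ties by accession id
    top = counts[order[:k]]
    bottom = counts[order[-k:]]
    stat = stats.mannwhitneyu(top, bottom, alternative="two-sided",
                              method="exact" if k <= 12 else "auto")
    return counts, float(stat.pvalue)


def maf_effect_profile(
    gwas_results: pd.DataFrame,
    p_threshold: float,
    n_bins: int = 5,
) -> Tuple[pd.DataFrame, dict]:
    """Minor-allele-oriented effects of significant variants versus MAF.

    Restricts to p < ``p_threshold``; each effect is re-signed to describe
    the minor allele (flipped when the alternate allele is the major one).
    The summary holds the Spearman correlation of MAF with |effect| and the
    positive/negative sign balance in MAF bins; both are NaN-flagged when
    fewer than 3 variants are significant.
    """
    sig = gwas_results[
        np.isfinite(gwas_results["p"]) & (gwas_results["p"] < p_threshold)
    ].copy()
    if len(sig) == 0:
        return sig.assign(minor_effect=[]), {"rho": np.nan, "rho_p": np.nan, "bins": None}
    # maf column is min(p_alt, 1-p_alt); orient beta to the minor allele
    alt_freq_is_minor = sig["maf"] == np.minimum(sig["maf"], 0.5)
    # recover alt allele frequency from dosage-based effect orientation:
    # the stored beta is per alt dosage; flip where alt is the major allele
    if "alt_freq" in sig.columns:
        flip = sig["alt_freq"] > 0.5
    else:
        flip = pd.Series(False, index=sig.index)  # alt assumed minor if unknown
    sig["minor_effect"] = np.where(flip, -sig["beta"], sig["beta"])
    table = sig[["id", "chrom", "pos", "maf", "minor_effect", "p"]].copy()
    table["sign"] = np.sign(table["minor_effect"])
    if len(table) < 3:
        return table, {"rho": np.nan, "rho_p": np.nan, "bins": None}
    rho, rho_p = stats.spearmanr(table["maf"], np.abs(table["minor_effect"]))
    bins = pd.cut(table["maf"], bins=n_bins)
    balance = table.groupby(bins, observed=True)["sign"].agg(
        pos=lambda s: int((s > 0).sum()), neg=lambda s: int((s < 0).sum())
    )
    return table, {"rho": float(rho), "rho_p": float(rho_p), "bins": balance}
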