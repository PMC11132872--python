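"""Genotype ingestion and population-genetic groundwork.

Covers the standard pre-association steps for a resequenced diversity
panel: genotype-level quality masking (GQ/DP), heterozygosity-based site
filtering, minor-allele frequencies, pairwise LD, windowed LD pruning,
Gabriel-style haplotype-block detection from EM-estimated D', principal
components, and the genomic relationship matrix with optional
leave-one-chromosome-out exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_and_filter_vcf",
    "apply_genotype_filters",
    "compute_maf",
    "ld_r2",
    "ld_prune",
    "LDBlock",
    "detect_ld_blocks",
    "pca",
    "GRM",
    "build_grm",
]


# ---------------------------------------------------------------------------
# VCF ingestion + genotype-level filters
# ---------------------------------------------------------------------------

def read_vcf(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame, List[str]]:
    """Raw read of a VCF: dosage, GQ, DP arrays plus variant metadata.

    Multiallelic records are split into biallelic records per alternate
    allele; genotypes carrying other alternates become missing in the split
    record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dos_rows, gq_rows, dp_rows, meta = [], [], [], []
    for rec in vcf:
        alts = rec.ALT or []
        gts = np.array(rec.genotypes or [], dtype=object)
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        gq = None if gq is None else np.asarray(gq, dtype=float).reshape(len(samples))
        dp = None if dp is None else np.asarray(dp, dtype=float).reshape(len(samples))
        for ai, alt in enumerate(alts, start=1):
            dose = np.full(len(samples), np.nan)
            het = np.zeros(len(samples), dtype=bool)
            for si, g in enumerate(gts):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    continue
                if (a not in (0, ai)) or (b not in (0, ai)):
                    continue  # carries another alternate: missing in this split
                dose[si] = (a == ai) + (b == ai)
                het[si] = a != b
            dos_rows.append(dose)
            gq_rows.append(np.full(len(samples), np.nan) if gq is None else gq)
            dp_rows.append(np.full(len(samples), np.nan) if dp is None else dp)
            vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
            if len(alts) > 1:
                vid = f"{vid}_{alt}"
            meta.append((vid, rec.CHROM, rec.POS, rec.REF, alt))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return (
        np.array(dos_rows).T if dos_rows else np.empty((len(samples), 0)),
        np.array(gq_rows).T if gq_rows else np.empty((len(samples), 0)),
        np.array(dp_rows).T if dp_rows else np.empty((len(samples), 0)),
        variants,
        samples,
    )


def apply_genotype_filters(
    dosages: np.ndarray,
    gq: Optional[np.ndarray],
    dp: Optional[np.ndarray],
    gq_min: int = 20,
    dp_het_min: int = 4,
    dp_hom_min: int = 2,
    het_site_frac: float = 0.02,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Mask low-confidence genotypes, then drop excessively heterozygous sites.

    Heterozygous calls with GQ < ``gq_min`` or DP < ``dp_het_min`` and
    homozygous calls with DP < ``dp_hom_min`` become missing.  Sites whose
    post-masking heterozygote fraction (over all accessions) exceeds
    ``het_site_frac`` are dropped entirely.  Masking and site dropping
    commute, so a single pass is exact.

    Returns (masked dosages, boolean keep mask per site, drop log).
    """
    dos = dosages.astype(float).copy()
    n = dos.shape[0]
    het = dos == 1
    hom = (dos == 0) | (dos == 2)
    if gq is not None:
        with np.errstate(invalid="ignore"):
            dos[het & (gq < gq_min)] = np.nan
    if dp is not None:
        with np.errstate(invalid="ignore"):
            dos[het & (dp < dp_het_min)] = np.nan
            dos[hom & (dp < dp_hom_min)] = np.nan
    het_frac = np.sum(dos == 1, axis=0) / n
    keep = het_frac <= het_site_frac
    log = pd.DataFrame(
        {"het_fraction": het_frac, "dropped_excess_het": ~keep}
    )
    return dos, keep, log


def read_and_filter_vcf(
    path,
    gq_min: int = 20,
    dp_het_min: int = 4,
    dp_hom_min: int = 2,
    het_site_frac: float = 0.02,
    missing_format_ok: bool = True,
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF and apply the genotype-level quality filters.

    Missing GQ/DP FORMAT fields are treated as passing when
    ``missing_format_ok`` (with a logged warning); otherwise they raise.
    """
    dos, gq, dp, variants, samples = read_vcf(path)
    if np.all(np.isnan(gq)) or np.all(np.isnan(dp)):
        if not missing_format_ok:
            raise ValueError(f"{path}: VCF lacks GQ/DP FORMAT fields")
        logger.warning("%s: missing GQ/DP fields; genotype filters treated as passing", path)
    masked, keep, log = apply_genotype_filters(
        dos, gq, dp, gq_min, dp_het_min, dp_hom_min, het_site_frac
    )
    log.index = variants["id"]
    g = GenotypeMatrix(
        masked[:, keep],
        variants.loc[keep].reset_index(drop=True),
        pd.DataFrame({"id": samples}),
    )
    g.variants["maf"] = compute_maf(g)
    return g, log


# ---------------------------------------------------------------------------
# allele frequencies and LD
# ---------------------------------------------------------------------------

def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per variant over non-missing alleles.

    All-missing variants get ``nan`` (flagged, not an error)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g.dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def missing_rate(g: GenotypeMatrix) -> np.ndarray:
    return np.mean(np.isnan(g.dosages), axis=0)


def ld_r2(g: GenotypeMatrix, a: int, b: int) -> float:
    """Squared Pearson correlation of dosages at variants ``a`` and ``b``
    over accessions non-missing at both.  Fewer than two shared calls, or a
    monomorphic variant, yields ``nan``."""
    x, y = g.dosages[:, a], g.dosages[:, b]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _dosage_corr_sq(X: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of columns with missing imputed to column means."""
    Xi = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    sd = Xi.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (Xi - Xi.mean(axis=0)) / sd
    r = (Z.T @ Z) / Z.shape[0]
    return r**2


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.2,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Variants failing the MAF/missingness screens are removed first; then,
    within each sliding window of ``window`` variants advanced by ``step``,
    the later-positioned member of any pair with r^2 > ``r2_max`` is
    dropped.  Returns surviving variant indices (into ``g``).
    """
    maf = compute_maf(g)
    miss = missing_rate(g)
    alive = np.ones(g.n_variants, dtype=bool)
    alive &= (maf >= maf_min) & (miss < miss_max) & ~np.isnan(maf)

    order = np.arange(g.n_variants)
    for chrom in pd.unique(g.variants["chrom"]):
        idx = g.chrom_indices(chrom)
        start = 0
        while start < len(idx):
            win = idx[start: start + window]
            live = win[alive[win]]
            if len(live) > 1:
                r2 = _dosage_corr_sq(g.dosages[:, live])
                for i in range(len(live)):
                    if not alive[live[i]]:
                        continue
                    for j in range(i + 1, len(live)):
                        if alive[live[j]] and r2[i, j] > r2_max:
                            alive[live[j]] = False
            start += step
            if start + window > len(idx) and start < len(idx) and start + step >= len(idx):
                break
    return order[alive]


# ---------------------------------------------------------------------------
# D' estimation and Gabriel blocks
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(x: np.ndarray, y: np.ndarray, n_iter: int = 50) -> Tuple[np.ndarray, float, float]:
    """EM haplotype-frequency estimation for an unphased diallelic pair.

    Returns haplotype frequencies (pAB, pAb, paB, pab) for alleles coded by
    dosage, plus marginal alt frequencies.  Only the double heterozygote is
    phase-ambiguous.
    """
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok].astype(int), y[ok].astype(int)
    n = len(x)
    if n == 0:
        raise ValueError("no shared genotyped accessions")
    pA = x.mean() / 2.0
    pB = y.mean() / 2.0
    # counts of known haplotypes
    n_dh = int(np.sum((x == 1) & (y == 1)))
    # haplotype counts excluding double hets: each individual contributes 2
    hAB = np.sum((x == 2) & (y == 2)) * 2 + np.sum((x == 2) & (y == 1)) + np.sum((x == 1) & (y == 2))
    hAb = np.sum((x == 2) & (y == 0)) * 2 + np.sum((x == 2) & (y == 1)) + np.sum((x == 1) & (y == 0))
    haB = np.sum((x == 0) & (y == 2)) * 2 + np.sum((x == 0) & (y == 1)) + np.sum((x == 1) & (y == 2))
    hab = np.sum((x == 0) & (y == 0)) * 2 + np.sum((x == 0) & (y == 1)) + np.sum((x == 1) & (y == 0))
    f = np.array([hAB, hAb, haB, hab], dtype=float) + 0.25
    f /= f.sum()
    total = 2.0 * n
    for _ in range(n_iter):
        # P(double het phased as AB/ab) vs (Ab/aB)
        num1 = f[0] * f[3]
        num2 = f[1] * f[2]
        w = num1 / (num1 + num2) if (num1 + num2) > 0 else 0.5
        c = np.array([hAB, hAb, haB, hab], dtype=float)
        c[0] += n_dh * w
        c[3] += n_dh * w
        c[1] += n_dh * (1 - w)
        c[2] += n_dh * (1 - w)
        f_new = c / total
        if np.max(np.abs(f_new - f)) < 1e-10:
            f = f_new
            break
        f = f_new
    return f, pA, pB


def dprime_ci(
    x: np.ndarray, y: np.ndarray, grid: int = 101
) -> Tuple[float, float, float]:
    """Point estimate and likelihood-based CI for |D'| of an unphased pair.

    Profiles the multinomial genotype-pair likelihood over |D'| in [0, 1]
    at the EM-estimated allele frequencies (Haploview's approach), returning
    (|D'|, lower 5% bound, upper 95% bound) from the normalised likelihood
    cumulative distribution.
    """
    f, pA, pB = _em_haplotype_freqs(x, y)
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0, 0.0, 1.0
    dprime = abs(D) / dmax
    sign = 1.0 if D >= 0 else -1.0

    ok = ~np.isnan(x) & ~np.isnan(y)
    xi, yi = x[ok].astype(int), y[ok].astype(int)
    # genotype-pair table counts
    counts = np.zeros((3, 3))
    for gx, gy in zip(xi, yi):
        counts[gx, gy] += 1

    dps = np.linspace(0.0, 1.0, grid)
    logl = np.empty(grid)
    for k, dp in enumerate(dps):
        Dk = sign * dp * dmax
        hf = np.array([
            pA * pB + Dk,
            pA * (1 - pB) - Dk,
            (1 - pA) * pB - Dk,
            (1 - pA) * (1 - pB) + Dk,
        ])
        hf = np.clip(hf, 1e-10, 1.0)
        # genotype-pair probs under random union of gametes
        pAB, pAb, paB, pab = hf
        probs = np.empty((3, 3))
        gam = {(1, 1): pAB, (1, 0): pAb, (0, 1): paB, (0, 0): pab}
        for gx in range(3):
            for gy in range(3):
                tot = 0.0
                for a1 in (0, 1):
                    for b1 in (0, 1):
                        for a2 in (0, 1):
                            for b2 in (0, 1):
                                if a1 + a2 == gx and b1 + b2 == gy:
                                    tot += gam[(a1, b1)] * gam[(a2, b2)]
                probs[gx, gy] = tot
        logl[k] = np.sum(counts * np.log(np.clip(probs, 1e-300, None)))
    lik = np.exp(logl - logl.max())
    cdf = np.cumsum(lik) / lik.sum()
    low = dps[int(np.searchsorted(cdf, 0.05))] if cdf[-1] > 0 else 0.0
    high = dps[min(int(np.searchsorted(cdf, 0.95)), grid - 1)]
    return float(dprime), float(low), float(high)


@dataclass
class LDBlock:
    chrom: str
    start_pos: int
    end_pos: int
    member_variants: List[int]  # indices into the genotype matrix

    @property
    def span(self) -> int:
        return self.end_pos - self.start_pos


def detect_ld_blocks(
    g: GenotypeMatrix,
    max_kb: float = 5000,
    strong_lowci: float = 0.70,
    strong_highci: float = 0.98,
    recomb_highci: float = 0.9,
    inform_frac: float = 0.8,
    max_pairs_span: int = 200,
) -> List[LDBlock]:
    """Gabriel-style haplotype blocks from D' confidence intervals.

    A pair is "strong LD" when its CI is [>= strong_lowci, >= strong_highci]
    and "recombination" when the upper bound < recomb_highci.  Candidate
    blocks are delimited by strong-LD endpoint pairs, accepted longest-first
    when informative pairs are at least ``inform_frac`` strong and the span
    does not exceed ``max_kb`` kb; accepted blocks do not overlap.
    """
    maf = compute_maf(g)
    blocks: List[LDBlock] = []
    for chrom in pd.unique(g.variants["chrom"]):
        idx = [i for i in g.chrom_indices(chrom) if maf[i] > 0]
        pos = g.variants["pos"].to_numpy()
        cis: dict = {}

        def pair_ci(i, j):
            if (i, j) not in cis:
                cis[(i, j)] = dprime_ci(g.dosages[:, i], g.dosages[:, j])
            return cis[(i, j)]

        candidates = []
        for a in range(len(idx)):
            for b in range(a + 1, min(a + 1 + max_pairs_span, len(idx))):
                i, j = idx[a], idx[b]
                if (pos[j] - pos[i]) > max_kb * 1000:
                    break
                _, lo, hi = pair_ci(i, j)
                if lo >= strong_lowci and hi >= strong_highci:
                    candidates.append((a, b))
        # longest span first
        candidates.sort(key=lambda ab: (pos[idx[ab[1]]] - pos[idx[ab[0]]]), reverse=True)
        taken = np.zeros(len(idx), dtype=bool)
        for a, b in candidates:
            if taken[a: b + 1].any():
                continue
            strong = recomb = 0
            for u in range(a, b + 1):
                for v in range(u + 1, b + 1):
                    _, lo, hi = pair_ci(idx[u], idx[v])
                    if lo >= strong_lowci and hi >= strong_highci:
                        strong += 1
                    elif hi < recomb_highci:
                        recomb += 1
            inform = strong + recomb
            if inform == 0 or strong / inform < inform_frac:
                continue
            taken[a: b + 1] = True
            members = sorted(idx[a: b + 1])
            blocks.append(
                LDBlock(str(chrom), int(pos[members[0]]), int(pos[members[-1]]), members)
            )
    blocks.sort(key=lambda bl: (bl.chrom, bl.start_pos))
    return blocks


# ---------------------------------------------------------------------------
# PCA and GRM
# ---------------------------------------------------------------------------

def _standardized(g: GenotypeMatrix, idx=None, maf_min: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    X = g.dosages if idx is None else g.dosages[:, idx]
    p = np.nanmean(X, axis=0) / 2.0
    keep = (np.minimum(p, 1 - p) > maf_min) & (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    Xi = np.where(np.isnan(X), 2 * p[None, :], X)
    Z = (Xi - 2 * p) / np.sqrt(2 * p * (1 - p))
    return Z, keep


def pca(g: GenotypeMatrix, n_components: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """Principal components of the standardized dosage matrix.

    Missing dosages are imputed to the variant mean.  Components are ordered
    by decreasing eigenvalue; each PC's sign is fixed so its
    largest-magnitude loading is positive.  Returns (scores, eigenvalues of
    the accession covariance).
    """
    if n_components > g.n_accessions:
        raise ValueError("n_components exceeds accession count")
    Z, _ = _standardized(g)
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    eigvals = s**2 / Zc.shape[0]
    scores = U * s
    for k in range(min(n_components, scores.shape[1])):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1
    return scores[:, :n_components], eigvals


@dataclass
class GRM:
    """Genomic relationship matrix with its variant bookkeeping."""

    matrix: np.ndarray
    variant_idx: np.ndarray
    excluded_chrom: Optional[str] = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_grm(
    g: GenotypeMatrix,
    exclude_chrom: Optional[str] = None,
    maf_min: float = 0.01,
    min_variants: int = 100,
) -> GRM:
    """Standardized-dosage GRM:
    A_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)),
    with missing dosages contributing their variant mean.
    """
    if exclude_chrom is not None:
        idx = np.flatnonzero((g.variants["chrom"] != exclude_chrom).to_numpy())
        if len(idx) == 0:
            raise ValueError(f"excluding {exclude_chrom} removes all variants")
    else:
        idx = np.arange(g.n_variants)
    Z, keep = _standardized(g, idx, maf_min=maf_min)
    if Z.shape[1] < min_variants:
        raise ValueError(
            f"only {Z.shape[1]} variants available for GRM (floor {min_variants})"
        )
    A = (Z @ Z.T) / Z.shape[1]
    return GRM(matrix=A, variant_idx=idx[keep], excluded_chrom=exclude_chrom)


def loco_grms(g: GenotypeMatrix, maf_min: float = 0.01, min_variants: int = 100) -> dict:
    """One GRM per chromosome, each excluding that chromosome."""
    return {
        str(chrom): build_grm(g, exclude_chrom=chrom, maf_min=maf_min, min_variants=min_variants)
        for chrom in pd.unique(g.variants["chrom"])
    }
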