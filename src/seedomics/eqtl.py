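"""Expression QTL mapping and downstream regulatory-architecture analysis.

Pipeline: TPM-based expression filtering -> per-gene rank-based inverse
normal transform -> mixed-model association against all variants with
leave-one-chromosome-out kinship -> LD clumping of suggestive associations
-> lead retention (study-wide 1/n threshold, minimum LD-proxy support) ->
merging of same-gene leads that share a haplotype block -> local/distal
classification at 1 Mb -> permutation-calibrated trans-hotspot detection
and open-chromatin enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GRM, compute_maf, detect_ld_blocks
from .mlm_assoc import Locus, clump, reml_null, _eig_grm
from .types import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "filter_expression",
    "quantile_normalize",
    "EQTLRecord",
    "map_eqtls",
    "classify_local_distal",
    "explained_variance",
    "Hotspot",
    "detect_hotspots",
    "ocr_enrichment",
    "summarize_eqtl_classes",
]


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def filter_expression(
    expr: ExpressionMatrix,
    tpm_min: float = 5.0,
    frac: float = 0.95,
    fold_min: float = 2.0,
) -> ExpressionMatrix:
    """Drop lowly/invariantly expressed genes.

    A gene survives when (a) its TPM reaches ``tpm_min`` in more than
    ``1 - frac`` of accessions (i.e. is not below ``tpm_min`` in more than
    ``frac`` of them) and (b) the ratio of its 95th to 5th expression
    percentile is at least ``fold_min``; a zero 5th percentile counts as
    passing the fold criterion.
    """
    tpm = expr.tpm
    n = tpm.shape[1]
    expressed = (tpm >= tpm_min).sum(axis=1) / n > (1.0 - frac)
    q95 = tpm.quantile(0.95, axis=1)
    q05 = tpm.quantile(0.05, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(q05 > 0, q95 / q05, np.inf)
    variable = pd.Series(fold >= fold_min, index=tpm.index)
    keep = expressed & variable
    if keep.sum() == 0:
        raise ValueError(
            f"no genes pass filters (expressed: {int(expressed.sum())}, "
            f"variable: {int(variable.sum())})"
        )
    return ExpressionMatrix(tpm=tpm.loc[keep], genes=expr.genes)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5)/n), ties by
    average rank.  Raises on constant input (ranks are undefined)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if np.nanstd(v) == 0:
        raise ValueError("cannot quantile-normalize a constant vector")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(v))


# ---------------------------------------------------------------------------
# eQTL mapping
# ---------------------------------------------------------------------------

@dataclass
class EQTLRecord:
    gene: str
    lead: str
    lead_idx: int
    chrom: str
    pos: int
    p: float
    n_proxies: int
    klass: str = ""  # "local" | "distal"
    r2_explained: float = float("nan")


def _bulk_assoc(
    g: GenotypeMatrix,
    Y: np.ndarray,
    grms: Dict[str, GRM],
) -> Tuple[np.ndarray, np.ndarray]:
    """Mixed-model beta and SE for every (gene, variant) pair.

    Rotated genotypes are computed once per chromosome and shared across all
    genes (rows of ``Y``), which keeps per-gene cost linear.
    """
    n_genes, n = Y.shape
    maf = compute_maf(g)
    beta = np.full((n_genes, g.n_variants), np.nan)
    se = np.full((n_genes, g.n_variants), np.nan)
    ones = np.ones(n)
    for chrom in pd.unique(g.variants["chrom"]):
        key = str(chrom) if str(chrom) in grms else "*"
        d, U = _eig_grm(grms[key])
        idx = g.chrom_indices(chrom)
        idx = idx[maf[idx] > 0]
        if len(idx) == 0:
            continue
        X = g.dosages[:, idx]
        X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
        Xt = U.T @ X
        ot = U.T @ ones
        Yt = Y @ U  # n_genes x n
        for gi in range(n_genes):
            yt = Yt[gi]
            h2, se2, sg2 = reml_null(Y[gi], d, U)
            v = h2 * d + (1 - h2)
            w = 1.0 / v
            s2 = se2 + sg2
            s_oo = np.sum(w * ot * ot)
            s_oy = np.sum(w * ot * yt)
            Wx = Xt * w[:, None]
            s_ox = ot @ Wx
            s_xx = np.einsum("ij,ij->j", Xt, Wx)
            s_xy = yt @ Wx
            det = s_oo * s_xx - s_ox**2
            with np.errstate(divide="ignore", invalid="ignore"):
                beta[gi, idx] = (s_oo * s_xy - s_ox * s_oy) / det
                se[gi, idx] = np.sqrt(s2 * s_oo / det)
    return beta, se


def map_eqtls(
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    grms: Dict[str, GRM],
    p_assoc: float = 1e-4,
    clump_r2: float = 0.2,
    clump_kb: float = 250,
    lead_p: Optional[float] = None,
    min_proxies: int = 2,
    strict_proxies: bool = False,
    block_params: Optional[dict] = None,
) -> List[EQTLRecord]:
    """Map eQTLs for every gene in ``expr`` (assumed filtered; rows are
    quantile-normalised internally).

    Per gene: association -> keep p < ``p_assoc`` -> greedy clump at
    (``clump_r2``, ``clump_kb``) -> retain leads with p < ``lead_p``
    (default 1/n_variants) carrying at least ``min_proxies`` LD proxies
    (strictly more when ``strict_proxies``) -> leads of the same gene that
    fall in one haplotype block are merged into the most significant lead.
    """
    if lead_p is None:
        lead_p = 1.0 / g.n_variants
    genes = expr.tpm.index.to_list()
    Y = np.vstack([quantile_normalize(expr.tpm.loc[gid].to_numpy()) for gid in genes])
    beta, se = _bulk_assoc(g, Y, grms)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(tstat))

    bp = dict(max_kb=5000, strong_lowci=0.70, strong_highci=0.98,
              recomb_highci=0.9, inform_frac=0.8)
    if block_params:
        bp.update(block_params)

    records: List[EQTLRecord] = []
    base = g.variants[["id", "chrom", "pos"]]
    need = min_proxies if not strict_proxies else min_proxies + 1
    for gi, gid in enumerate(genes):
        pv = pvals[gi]
        hits = np.flatnonzero(pv < p_assoc)
        if len(hits) == 0:
            continue
        res = base.iloc[hits].copy()
        res["p"] = pv[hits]
        loci = clump(res, g, p1=p_assoc, p2=p_assoc, r2=clump_r2, kb=clump_kb)
        leads = [
            lc for lc in loci
            if lc.p < lead_p and len(lc.members) >= need
        ]
        if not leads:
            continue
        if len(leads) > 1:
            leads = _merge_leads_by_block(leads, g, bp)
        for lc in leads:
            records.append(
                EQTLRecord(
                    gene=gid, lead=lc.lead, lead_idx=lc.lead_idx,
                    chrom=lc.chrom, pos=lc.pos, p=lc.p,
                    n_proxies=len(lc.members),
                )
            )
    return records


def _merge_leads_by_block(leads: List[Locus], g: GenotypeMatrix, bp: dict) -> List[Locus]:
    """Merge same-gene leads that share a haplotype block; the minimum-p lead
    represents the merged signal.  Blocks are detected on the lead variants
    only (the merge question only involves them)."""
    sub = g.take_variants(sorted({lc.lead_idx for lc in leads}))
    blocks = detect_ld_blocks(sub, **bp)
    pos_to_block: Dict[Tuple[str, int], int] = {}
    for bi, blk in enumerate(blocks):
        for vi in blk.member_variants:
            pos_to_block[(blk.chrom, int(sub.variants.loc[vi, "pos"]))] = bi
    kept: Dict[int, Locus] = {}
    singles: List[Locus] = []
    for lc in sorted(leads, key=lambda x: x.p):
        bi = pos_to_block.get((lc.chrom, lc.pos))
        if bi is None:
            singles.append(lc)
        elif bi not in kept:
            kept[bi] = lc
    return sorted(kept.values(), key=lambda x: x.p) + singles


# ---------------------------------------------------------------------------
# classification and effect size
# ---------------------------------------------------------------------------

def classify_local_distal(
    records: Sequence[EQTLRecord],
    genes: pd.DataFrame,
    cutoff: int = 1_000_000,
) -> List[EQTLRecord]:
    """Classify each record as local (same chromosome, within ``cutoff`` of
    the gene span, boundary inclusive) or distal."""
    gtab = genes.set_index("gene_id") if genes.index.name != "gene_id" else genes
    for rec in records:
        if rec.gene not in gtab.index:
            raise KeyError(f"unknown gene id {rec.gene}")
        row = gtab.loc[rec.gene]
        if rec.chrom != row["chrom"]:
            rec.klass = "distal"
            continue
        if row["start"] <= rec.pos <= row["end"]:
            dist = 0
        else:
            dist = min(abs(rec.pos - row["start"]), abs(rec.pos - row["end"]))
        rec.klass = "local" if dist <= cutoff else "distal"
    return list(records)


def explained_variance(
    record: EQTLRecord, g: GenotypeMatrix, expr: ExpressionMatrix
) -> float:
    """Squared correlation between the lead dosage and the gene's
    quantile-normalised expression."""
    x = g.dosages[:, record.lead_idx]
    if np.nanstd(x) == 0:
        raise ValueError(f"lead {record.lead} is monomorphic")
    y = quantile_normalize(expr.tpm.loc[record.gene].to_numpy())
    ok = ~np.isnan(x)
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    record.r2_explained = float(r * r)
    return record.r2_explained


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    n_distal_egenes: int
    egenes: List[str]
    passes: bool


def _window_gene_counts(
    pos: np.ndarray, gene_codes: np.ndarray, length: int, window: int, step: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Distinct-gene counts per sliding window on one chromosome."""
    starts = np.arange(0, max(length - window, 0) + 1, step)
    order = np.argsort(pos)
    pos_s, genes_s = pos[order], gene_codes[order]
    counts = np.empty(len(starts), dtype=int)
    lo = np.searchsorted(pos_s, starts)
    hi = np.searchsorted(pos_s, starts + window, side="right")
    for k in range(len(starts)):
        counts[k] = len(np.unique(genes_s[lo[k]: hi[k]]))
    return starts, counts


def detect_hotspots(
    records: Sequence[EQTLRecord],
    genome: Dict[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    merge: bool = True,
) -> Tuple[List[Hotspot], float]:
    """Permutation-calibrated trans-eQTL hotspot windows.

    Per sliding window, count distinct distal eGenes whose lead falls in the
    window.  The null shuffles distal-eQTL lead positions uniformly within
    their chromosome (gene links kept, per-chromosome counts preserved) and
    records the genome-wide maximum window count; the threshold is the
    (1 - alpha) quantile of that maximum distribution and windows counting
    strictly more than it pass.  Overlapping passing windows merge.
    """
    distal = [r for r in records if r.klass == "distal"]
    if not distal:
        return [], 0.0
    rng = np.random.default_rng(seed)
    genes_u = {gid: i for i, gid in enumerate(sorted({r.gene for r in distal}))}
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome:
        rs = [r for r in distal if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.pos for r in rs], dtype=float),
            np.array([genes_u[r.gene] for r in rs], dtype=int),
        )

    obs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in genome.items():
        pos, codes = by_chrom[chrom]
        obs[chrom] = _window_gene_counts(pos, codes, length, window, step)

    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        best = 0
        for chrom, length in genome.items():
            pos, codes = by_chrom[chrom]
            if len(pos) == 0:
                continue
            rpos = rng.uniform(0, length, size=len(pos))
            _, counts = _window_gene_counts(rpos, codes, length, window, step)
            if counts.size:
                best = max(best, int(counts.max()))
        null_max[b] = best
    threshold = float(np.quantile(null_max, 1 - alpha))

    hotspots: List[Hotspot] = []
    for chrom, length in genome.items():
        starts, counts = obs[chrom]
        flagged = np.flatnonzero(counts > threshold)
        if len(flagged) == 0:
            continue
        if merge:
            groups: List[List[int]] = [[flagged[0]]]
            for f in flagged[1:]:
                if starts[f] <= starts[groups[-1][-1]] + window:
                    groups[-1].append(f)
                else:
                    groups.append([f])
        else:
            groups = [[f] for f in flagged]
        pos, codes = by_chrom[chrom]
        inv_genes = {v: k for k, v in genes_u.items()}
        for grp in groups:
            s = int(starts[grp[0]])
            e = int(starts[grp[-1]] + window)
            inwin = (pos >= s) & (pos < e)
            gset = sorted({inv_genes[c] for c in codes[inwin]})
            hotspots.append(Hotspot(chrom, s, e, len(gset), gset, True))
    return hotspots, threshold


# ---------------------------------------------------------------------------
# OCR enrichment
# ---------------------------------------------------------------------------

def _overlap_count(lead_pos: Dict[str, np.ndarray], intervals: pd.DataFrame) -> int:
    total = 0
    for chrom, sub in intervals.groupby("chrom"):
        pos = lead_pos.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # BED half-open [start, end); positions are 1-based -> 0-based = pos-1
        p0 = pos - 1
        j = np.searchsorted(starts, p0, side="right") - 1
        ok = j >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = p0[ok] < ends[j[ok]]
        # intervals may overlap each other: check previous few too
        for back in (2, 3):
            jj = j - (back - 1)
            ok2 = jj >= 0
            hit[ok2] |= (p0[ok2] >= starts[jj[ok2]]) & (p0[ok2] < ends[jj[ok2]])
        total += int(hit.sum())
    return total


def ocr_enrichment(
    leads: Sequence[EQTLRecord],
    ocr: pd.DataFrame,
    genome: Dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[int, float, Tuple[float, float], float]:
    """Enrichment of eQTL leads in open-chromatin intervals against a null
    of randomly relocated intervals (lengths preserved, uniform placement on
    the same chromosome).  Returns (observed, null mean, null 95% band,
    empirical p = (1 + #null >= obs) / (n_perm + 1))."""
    for _, row in ocr.iterrows():
        if row["end"] > genome[row["chrom"]]:
            raise ValueError(f"interval beyond chromosome end: {tuple(row)}")
    rng = np.random.default_rng(seed)
    lead_pos = {
        chrom: np.array([r.pos for r in leads if r.chrom == chrom], dtype=int)
        for chrom in genome
    }
    observed = _overlap_count(lead_pos, ocr)
    null = np.empty(n_perm)
    lengths = (ocr["end"] - ocr["start"]).to_numpy()
    chroms = ocr["chrom"].to_numpy()
    for b in range(n_perm):
        starts = np.array([
            rng.integers(0, genome[c] - L) if genome[c] > L else 0
            for c, L in zip(chroms, lengths)
        ])
        perm = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})
        null[b] = _overlap_count(lead_pos, perm)
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    ci = (float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975)))
    return observed, float(null.mean()), ci, float(p)


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summarize_eqtl_classes(records: Sequence[EQTLRecord]) -> dict:
    """Counts and integer percentages of local/distal eQTLs and of eGenes
    regulated by local-only / distal-only / both classes."""
    total = len(records)
    n_local = sum(1 for r in records if r.klass == "local")
    n_distal = sum(1 for r in records if r.klass == "distal")
    gene_classes: Dict[str, set] = {}
    for r in records:
        gene_classes.setdefault(r.gene, set()).add(r.klass)
    n_genes = len(gene_classes)
    local_only = sum(1 for s in gene_classes.values() if s == {"local"})
    distal_only = sum(1 for s in gene_classes.values() if s == {"distal"})
    both = sum(1 for s in gene_classes.values() if s == {"local", "distal"})
    pct = lambda c, t: _round_half_away(100.0 * c / t) if t else 0
    return {
        "n_eqtls": total,
        "n_local": n_local,
        "n_distal": n_distal,
        "pct_local": pct(n_local, total),
        "pct_distal": pct(n_distal, total),
        "n_egenes": n_genes,
        "n_local_only": local_only,
        "n_distal_only": distal_only,
        "n_both": both,
        "pct_local_only": pct(local_only, n_genes),
        "pct_distal_only": pct(distal_only, n_genes),
        "pct_both": pct(both, n_genes),
    }
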