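"""Selection-scan statistics across domestication panels.

Windowed nucleotide diversity (per-bp pi over the full window length, the
convention of the common VCF window tools), pi-ratio sweep scans against
empirical genome-wide quantile thresholds, windowed Weir-Cockerham FST
(ratio of summed variance components), and haplotype spectra over a set of
defining variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

__all__ = [
    "windowed_pi",
    "pi_ratio_scan",
    "windowed_fst",
    "HaplotypeSpectrum",
    "haplotype_spectrum",
]


def _windows(length: int, window_bp: int, step_bp: int) -> np.ndarray:
    starts = np.arange(0, max(length - window_bp, 0) + 1, step_bp)
    return starts


def site_pi(dosages: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity 2p(1-p) * n/(n-1) over non-missing
    alleles (n = allele count)."""
    n_allele = 2.0 * np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / n_allele
        pi = 2.0 * p * (1.0 - p) * n_allele / (n_allele - 1.0)
    pi[n_allele < 2] = np.nan
    return pi


def windowed_pi(
    g: GenotypeMatrix,
    genome: Dict[str, int],
    window_bp: int = 100_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Per-window pi: sum of per-site heterozygosity divided by the window
    length in bp.  Windows with zero genotyped sites get pi = 0 and a flag."""
    if g.n_accessions < 2:
        raise ValueError("panel needs at least 2 accessions")
    spi = site_pi(g.dosages)
    rows = []
    pos_all = g.variants["pos"].to_numpy()
    for chrom, length in genome.items():
        idx = g.chrom_indices(chrom)
        pos = pos_all[idx]
        vals = spi[idx]
        order = np.argsort(pos)
        pos, vals = pos[order], vals[order]
        for s in _windows(length, window_bp, step_bp):
            lo = np.searchsorted(pos, s + 1)  # positions are 1-based
            hi = np.searchsorted(pos, s + window_bp, side="right")
            seg = vals[lo:hi]
            seg = seg[~np.isnan(seg)]
            rows.append(
                (chrom, int(s), int(s + window_bp),
                 float(seg.sum() / window_bp), len(seg) == 0)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi", "no_sites"])


def pi_ratio_scan(
    pi_a: pd.DataFrame,
    pi_b: pd.DataFrame,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Ratio pi_a / pi_b per window with the genome-wide (1 - top_frac)
    quantile threshold; windows at or above the threshold are flagged.

    0/0 windows are excluded (NaN); x/0 is capped at the largest finite
    ratio and flagged ``capped``.
    """
    key = ["chrom", "start", "end"]
    if not pi_a[key].equals(pi_b[key]):
        raise ValueError("window tilings differ between panels")
    out = pi_a[key].copy()
    a = pi_a["pi"].to_numpy()
    b = pi_b["pi"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    capped = (b == 0) & (a > 0)
    ratio[(a == 0) & (b == 0)] = np.nan
    finite_max = np.nanmax(ratio[np.isfinite(ratio)]) if np.any(np.isfinite(ratio)) else np.nan
    ratio[capped] = finite_max
    out["ratio"] = ratio
    out["capped"] = capped
    finite = ratio[np.isfinite(ratio)]
    threshold = float(np.quantile(finite, 1 - top_frac)) if len(finite) else float("nan")
    out["flagged"] = np.isfinite(ratio) & (ratio >= threshold)
    out.attrs["threshold"] = threshold
    return out


def _wc_components(
    d_a: np.ndarray, d_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two
    populations of diploids, from dosage matrices."""
    r = 2.0
    n1 = np.sum(~np.isnan(d_a), axis=0).astype(float)
    n2 = np.sum(~np.isnan(d_b), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(d_a, axis=0) / (2 * n1)
        p2 = np.nansum(d_b, axis=0) / (2 * n2)
        h1 = np.nansum(d_a == 1, axis=0) / n1
        h2 = np.nansum(d_b == 1, axis=0) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def windowed_fst(
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix,
    genome: Dict[str, int],
    window_bp: int = 100_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST: per-site variance components summed
    within each window, FST = sum(a) / sum(a + b + c).  Windows without
    usable polymorphic sites are NaN-flagged; negative aggregates are
    reported as computed."""
    if panel_a.n_accessions < 2 or panel_b.n_accessions < 2:
        raise ValueError("both panels need at least 2 accessions")
    if not panel_a.variants["id"].equals(panel_b.variants["id"]):
        raise ValueError("panels must share one variant set")
    a, b, c = _wc_components(panel_a.dosages, panel_b.dosages)
    tot = a + b + c
    pos_all = panel_a.variants["pos"].to_numpy()
    rows = []
    for chrom, length in genome.items():
        idx = panel_a.chrom_indices(chrom)
        pos = pos_all[idx]
        order = np.argsort(pos)
        pos = pos[order]
        av, tv = a[idx][order], tot[idx][order]
        for s in _windows(length, window_bp, step_bp):
            lo = np.searchsorted(pos, s + 1)
            hi = np.searchsorted(pos, s + window_bp, side="right")
            seg_a, seg_t = av[lo:hi], tv[lo:hi]
            ok = ~np.isnan(seg_t) & (seg_t != 0)
            if not np.any(ok):
                rows.append((chrom, int(s), int(s + window_bp), np.nan, True))
                continue
            fst = float(np.sum(seg_a[ok]) / np.sum(seg_t[ok]))
            rows.append((chrom, int(s), int(s + window_bp), fst, False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "undefined"])


@dataclass
class HaplotypeSpectrum:
    defining_variants: List[str]
    haplotypes: Dict[str, str]  # haplotype id -> allele string
    counts: pd.DataFrame  # haplotype id x panel
    frequencies: pd.DataFrame


def haplotype_spectrum(
    panels: Dict[str, GenotypeMatrix],
    defining_variants: Sequence[str],
    max_haplotypes: int = 4,
) -> HaplotypeSpectrum:
    """Haplotype spectrum over a set of defining variants across panels.

    Phased panels (those carrying a haplotype matrix) are counted at the
    haplotype level; unphased panels fall back to unambiguous diplotype
    strings with heterozygous-carrying accessions excluded from the
    denominator.  Haplotypes are ranked by pooled frequency; those past
    ``max_haplotypes`` pool into "other".
    """
    counts: Dict[str, Dict[str, int]] = {}
    totals: Dict[str, int] = {}
    for name, panel in panels.items():
        ids = panel.variants["id"].tolist()
        try:
            cols = [ids.index(v) for v in defining_variants]
        except ValueError as exc:
            raise ValueError(f"defining variant missing from panel {name}") from exc
        c: Dict[str, int] = {}
        if panel.haplotypes is not None:
            H = panel.haplotypes[:, cols]
            for row in H:
                s = "".join(str(int(x)) for x in row)
                c[s] = c.get(s, 0) + 1
            totals[name] = H.shape[0]
        else:
            D = panel.dosages[:, cols]
            total = 0
            for row in D:
                if np.any(np.isnan(row)) or np.any(row == 1):
                    continue  # missing or phase-ambiguous
                s = "".join(str(int(x // 2)) for x in row)
                c[s] = c.get(s, 0) + 2
                total += 2
            totals[name] = total
        counts[name] = c

    pooled: Dict[str, int] = {}
    for c in counts.values():
        for s, k in c.items():
            pooled[s] = pooled.get(s, 0) + k
    ranked = sorted(pooled, key=lambda s: -pooled[s])
    if not ranked:
        raise ValueError("region yields no countable haplotypes")
    keep = ranked[:max_haplotypes]
    hap_ids = {s: f"Hap{i + 1}" for i, s in enumerate(keep)}

    panel_names = list(panels)
    cnt = pd.DataFrame(0, index=[hap_ids[s] for s in keep] + ["other"], columns=panel_names)
    for name in panel_names:
        for s, k in counts[name].items():
            row = hap_ids.get(s, "other")
            cnt.loc[row, name] += k
    freq = cnt / pd.Series(totals)
    return HaplotypeSpectrum(
        defining_variants=list(defining_variants),
        haplotypes={hap_ids[s]: s for s in keep},
        counts=cnt,
        frequencies=freq,
    )
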