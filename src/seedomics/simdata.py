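"""Synthetic study generator for a structured crop diversity panel.

Generates genotypes, seed-tissue expression, paired seed traits and
wild/landrace/cultivar panels with the statistical structure the downstream
analyses assume, together with a ground-truth table used for
parameter-recovery testing:

* population structure — K subpopulations with Balding–Nichols allele
  frequencies around shared ancestral frequencies at a target FST;
* linkage disequilibrium — a Gaussian-copula AR(1) latent process per
  haplotype whose correlation decays as ``exp(-distance / ld_decay_bp)``,
  thresholded at the subpopulation allele frequency (marginals exact);
* local eQTLs planted within 100 kb of gene TSSs, trans-hotspot regulator
  variants each driving a set of genes more than 1 Mb away, and coexpressed
  modules driven by heavy-tailed latent factors (non-Gaussian, so that
  independent component analysis can recover them);
* two quantitative traits with a chosen genetic correlation and
  heritabilities, partly mediated through designated gene expression;
* three domestication panels sharing one variant set, with a haplotype
  whose frequency is swept upward from wild to cultivar and local diversity
  correspondingly reduced.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimStudy",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_traits",
    "simulate_panels",
    "simulate_study",
    "write_fixture_set",
]

TRAITS = ("seed_weight", "oil_content")


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults emulate a mid-sized
    resequenced soybean panel scaled to desktop size."""

    n_accessions: int = 300
    n_chromosomes: int = 4
    chrom_length_bp: int = 20_000_000
    n_variants: int = 4000
    n_subpops: int = 4
    target_fst: float = 0.1
    # within-subpopulation family drift: real panels carry a continuum of
    # kinship, which is what identifies variance components in REML
    family_size: int = 8
    family_fst: float = 0.15
    maf_floor: float = 0.05
    ld_decay_bp: float = 150_000.0  # cultivated soybean has long-range LD
    n_genes: int = 800
    frac_local_egenes: float = 0.15
    n_hotspots: int = 2
    genes_per_hotspot: int = 20
    n_modules: int = 3
    module_size: int = 60
    trait_h2: Tuple[float, float] = (0.5, 0.5)
    trait_rg: float = 0.4
    n_trait_causal: int = 300
    n_mediator_genes: int = 2
    noise_sd: float = 0.5
    local_r2: float = 0.2  # target variance fraction of a planted local eQTL
    hotspot_r2: float = 0.12
    module_sd: float = 1.0
    # shared module-0 correlation with both traits; sized so the link
    # stays q<0.05 after the attenuation of ICA component estimation
    module_trait_r: float = 0.4
    # variance share of the hotspot-0 regulator genotype in module 0's
    # latent factor; sized so the eigengene association is genome-wide
    # detectable at the simulated sample size
    module_regulator_r2: float = 0.35
    n_background_factors: int = 15
    background_share: float = 0.6  # fraction of noise variance that is shared
    low_expr_frac: float = 0.05
    missing_frac: float = 0.02  # genotype cells given filter-tripping GQ/DP
    panel_size: int = 200
    sweep_freqs: Tuple[float, float, float] = (0.3, 0.8, 0.95)
    sweep_region_bp: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_accessions", "n_chromosomes", "chrom_length_bp", "n_variants",
            "n_subpops", "n_genes", "n_hotspots", "genes_per_hotspot",
            "n_modules", "panel_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in (0, 0.5)")
        if not (0.0 <= self.frac_local_egenes <= 1.0):
            raise ValueError("frac_local_egenes must be a fraction")
        if abs(self.trait_rg) > 1.0:
            raise ValueError("trait_rg must be in [-1, 1]")
        if not all(0.0 <= h <= 1.0 for h in self.trait_h2):
            raise ValueError("heritabilities must be fractions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_variants < self.n_chromosomes:
            raise ValueError("n_variants must be >= n_chromosomes")


@dataclass
class TruthTable:
    """Ground truth of every planted signal; the parameter-recovery oracle."""

    planted_local_eqtls: List[Tuple[str, str, float]] = field(default_factory=list)
    planted_hotspots: List[Tuple[str, List[str], Dict[str, float]]] = field(
        default_factory=list
    )
    module_membership: Dict[str, int] = field(default_factory=dict)
    module_factors: Optional[np.ndarray] = None  # accessions x modules
    trait_variant_effects: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    genetic_values: Optional[pd.DataFrame] = None  # accession x trait
    mediator_genes: List[str] = field(default_factory=list)
    panel_swept_haplotype: Optional[dict] = None
    # non-genetic part of module 0's factor; drives the shared trait
    # component so the planted polygenic rg stays uncontaminated
    module_trait_profile: Optional[np.ndarray] = None


@dataclass
class SimStudy:
    """One fully simulated study: all matrices plus the truth table."""

    config: SimConfig
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    truth: TruthTable
    ocr: Optional[pd.DataFrame] = None  # chrom, start, end (0-based half-open)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _chrom_counts(n_items: int, n_chrom: int) -> np.ndarray:
    base = np.full(n_chrom, n_items // n_chrom, dtype=int)
    base[: n_items % n_chrom] += 1
    return base

def _subpop_labels(n: int, k: int) -> np.ndarray:
    sizes = _chrom_counts(n, k)
    return np.repeat(np.arange(k), sizes)


def simulate_genotypes(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw a structured, LD-bearing diploid dosage matrix.

    Subpopulation allele frequencies follow a Balding–Nichols model around
    uniform ancestral frequencies; within-chromosome LD comes from an AR(1)
    Gaussian copula on each haplotype with correlation
    ``exp(-distance/ld_decay_bp)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, k = cfg.n_accessions, cfg.n_subpops
    counts = _chrom_counts(cfg.n_variants, cfg.n_chromosomes)

    chroms, positions = [], []
    for c, m_c in enumerate(counts):
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp), size=m_c, replace=False))
        chroms.append(np.full(m_c, c + 1))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    m = cfg.n_variants

    labels = _subpop_labels(n, k)
    # families nest inside subpopulations; unit = one family
    fam_size = max(int(cfg.family_size), 1)
    fam_labels = np.empty(n, dtype=int)
    fam_parent = []  # family -> subpop
    fid = 0
    for s in range(k):
        members = np.flatnonzero(labels == s)
        for off in range(0, len(members), fam_size):
            fam_labels[members[off: off + fam_size]] = fid
            fam_parent.append(s)
            fid += 1
    fam_parent = np.asarray(fam_parent)
    n_fam = fid
    hap_labels = np.repeat(fam_labels, 2)
    H = 2 * n

    def _ar1(shape, rho):
        """Stationary standard-normal AR(1) along the last axis with
        per-step correlations ``rho`` (length last-axis - 1)."""
        e = rng.standard_normal(shape)
        z = np.empty_like(e)
        z[..., 0] = e[..., 0]
        scale = np.sqrt(1 - rho**2)
        for j in range(1, shape[-1]):
            z[..., j] = rho[j - 1] * z[..., j - 1] + scale[j - 1] * e[..., j]
        return z

    # Allele frequencies vary smoothly along each chromosome (matching the
    # Gaussian-copula correlation of the haplotypes): uncorrelated per-site
    # frequencies would cap indicator correlation far below the latent
    # correlation and suppress realised LD.  The copula leaves the
    # marginals untouched, so the MAF spectrum stays uniform on
    # (maf_floor, 1 - maf_floor) and subpopulation frequencies stay
    # Balding-Nichols around the ancestral value.
    hap = np.empty((H, m), dtype=np.int8)
    p_anc = np.empty(m)
    p_sub = np.empty((k, m))
    start = 0
    for c, m_c in enumerate(counts):
        sl = slice(start, start + m_c)
        d = np.diff(pos_arr[sl]).astype(float)
        rho = np.exp(-d / cfg.ld_decay_bp)

        u_anc = stats.norm.cdf(_ar1((m_c,), rho))
        p_anc_c = cfg.maf_floor + (1 - 2 * cfg.maf_floor) * u_anc
        p_anc[sl] = p_anc_c

        if cfg.target_fst > 0:
            f = cfg.target_fst
            a = p_anc_c * (1 - f) / f
            b = (1 - p_anc_c) * (1 - f) / f
            u_sub = stats.norm.cdf(_ar1((k, m_c), rho))
            p_sub_c = np.clip(stats.beta.ppf(u_sub, a, b), 1e-4, 1 - 1e-4)
        else:
            p_sub_c = np.tile(p_anc_c, (k, 1))
        p_sub[:, sl] = p_sub_c

        if cfg.family_fst > 0 and fam_size > 1:
            ff = cfg.family_fst
            pp = p_sub_c[fam_parent]  # n_fam x m_c
            af = pp * (1 - ff) / ff
            bf = (1 - pp) * (1 - ff) / ff
            u_fam = stats.norm.cdf(_ar1((n_fam, m_c), rho))
            p_unit_c = np.clip(stats.beta.ppf(u_fam, af, bf), 1e-4, 1 - 1e-4)
        else:
            p_unit_c = p_sub_c[fam_parent]

        thresholds = stats.norm.ppf(p_unit_c)  # allele=1 iff latent < Phi^-1(p)
        z = _ar1((H, m_c), rho)
        hap[:, sl] = (z < thresholds[hap_labels]).astype(np.int8)
        start += m_c

    dos = (hap[0::2] + hap[1::2]).astype(float)
    variants = pd.DataFrame(
        {
            "id": [f"chr{c}_{p}" for c, p in zip(chrom_arr, pos_arr)],
            "chrom": [f"chr{c}" for c in chrom_arr],
            "pos": pos_arr,
            "ref": "A",
            "alt": "T",
        }
    )
    accessions = pd.DataFrame(
        {
            "id": [f"acc{i:04d}" for i in range(n)],
            "subpop": labels,
            "family": fam_labels,
        }
    )
    return GenotypeMatrix(dos, variants, accessions, haplotypes=hap)


# ---------------------------------------------------------------------------
# gene coordinates and expression
# ---------------------------------------------------------------------------

def gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spaced gene models; strand alternates, gene length 3 kb."""
    counts = _chrom_counts(cfg.n_genes, cfg.n_chromosomes)
    rows = []
    g = 0
    for c, k_c in enumerate(counts):
        spacing = cfg.chrom_length_bp // (k_c + 1)
        for j in range(k_c):
            start = (j + 1) * spacing
            strand = "+" if g % 2 == 0 else "-"
            rows.append((f"gene{g:05d}", f"chr{c + 1}", start, start + 3000, strand))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _nearest_variant(
    geno: GenotypeMatrix,
    chrom: str,
    pos: int,
    max_dist: int,
    mask: Optional[np.ndarray] = None,
) -> Optional[int]:
    idx = geno.chrom_indices(chrom)
    if mask is not None:
        idx = idx[mask[idx]]
    if len(idx) == 0:
        return None
    d = np.abs(geno.variants["pos"].to_numpy()[idx] - pos)
    j = int(np.argmin(d))
    return int(idx[j]) if d[j] <= max_dist else None


def _taggable_mask(
    geno: GenotypeMatrix,
    r2_min: float = 0.6,
    radius_bp: int = 250_000,
    min_proxies: int = 2,
) -> np.ndarray:
    """Variants with at least ``min_proxies`` neighbours in strong LD
    (r^2 >= ``r2_min`` within ``radius_bp``).  Causal variants are planted
    only at taggable sites: a reportable association peak needs proxies
    that are themselves significant, which requires the proxy's LD share
    of the planted variance (r^2_LD x planted r^2) to clear the
    association threshold with margin at the simulated sample size."""
    m = geno.n_variants
    pos = geno.variants["pos"].to_numpy()
    counts = np.zeros(m, dtype=int)
    X = geno.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]
    for chrom in geno.variants["chrom"].unique():
        idx = geno.chrom_indices(chrom)
        Zc, pc = Z[:, idx], pos[idx]
        for off in range(1, len(idx)):
            gap = pc[off:] - pc[:-off]
            close = gap <= radius_bp
            if not close.any():
                break
            r = (Zc[:, off:] * Zc[:, :-off]).sum(axis=0) / n
            hit = close & (r**2 >= r2_min)
            counts[idx[:-off][hit]] += 1
            counts[idx[off:][hit]] += 1
    return counts >= min_proxies


def simulate_expression(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[TruthTable] = None,
) -> Tuple[ExpressionMatrix, TruthTable]:
    """Plant local eQTLs, trans hotspots and coexpression modules.

    Expression is built on the log scale as
    ``baseline + local + hotspot + module factors + N(0, noise_sd)`` and
    exponentiated to pseudo-TPM, so the TPM-based low-expression filter is
    exercisable downstream.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    truth = TruthTable() if truth is None else truth
    n = geno.n_accessions
    genes = gene_table(cfg)
    n_genes = len(genes)

    n_local = int(round(cfg.frac_local_egenes * cfg.n_genes))
    if cfg.frac_local_egenes > 0 and n_local < 1:
        raise ValueError("frac_local_egenes * n_genes must be >= 1 when nonzero")

    log_expr = np.zeros((n_genes, n))
    baseline = rng.normal(np.log(50.0), 1.0, size=n_genes)
    low = rng.random(n_genes) < cfg.low_expr_frac
    baseline[low] = np.log(0.5)
    log_expr += baseline[:, None]

    tss = genes["start"].where(genes["strand"] == "+", genes["end"]).to_numpy()
    gene_order = rng.permutation(n_genes)

    # --- local eQTLs: effect sized so the variant explains ~local_r2 of the
    #     gene's variance at the configured noise level
    taggable = _taggable_mask(geno)
    local_genes = []
    for gi in gene_order:
        if len(local_genes) >= n_local:
            break
        vi = _nearest_variant(
            geno, genes.loc[gi, "chrom"], int(tss[gi]), 100_000, mask=taggable
        )
        if vi is None:
            continue
        x = geno.dosages[:, vi]
        vx = np.var(x)
        if vx < 1e-8:
            continue
        r2 = cfg.local_r2
        b = np.sqrt(r2 / (1 - r2)) * cfg.noise_sd / np.sqrt(vx)
        b *= rng.choice([-1.0, 1.0])
        log_expr[gi] += b * x
        truth.planted_local_eqtls.append(
            (geno.variants.loc[vi, "id"], genes.loc[gi, "gene_id"], float(b))
        )
        local_genes.append(gi)
    local_set = set(local_genes)

    # --- module memberships (disjoint blocks of non-local genes)
    pool = [g for g in gene_order if g not in local_set]
    factors = np.empty((n, cfg.n_modules))
    module_genes: List[List[int]] = []
    cursor = 0
    for mmod in range(cfg.n_modules):
        members = pool[cursor: cursor + cfg.module_size]
        cursor += cfg.module_size
        module_genes.append(list(members))
        for gi in members:
            truth.module_membership[genes.loc[gi, "gene_id"]] = mmod

    # --- hotspot regulators, each driving genes_per_hotspot genes > 1 Mb away.
    #     Hotspot 0 drives module 0's genes through the module's latent factor
    #     (coexpression with a shared trans regulator); other hotspots act
    #     through independent per-target effects.
    var_pos = geno.variants["pos"].to_numpy()
    var_chrom = geno.variants["chrom"].to_numpy()
    gene_chrom = genes["chrom"].to_numpy()
    reg_idx: List[int] = []
    maf_all = np.nanmean(geno.dosages, axis=0) / 2.0
    cand = np.flatnonzero((np.minimum(maf_all, 1 - maf_all) > 0.15) & taggable)
    cand = rng.permutation(cand)
    for h in range(cfg.n_hotspots):
        reg_idx.append(int(cand[h]))

    def far_genes(vi: int, k: int, exclude: set) -> List[int]:
        far = [
            gi for gi in gene_order
            if gi not in exclude
            and (
                gene_chrom[gi] != var_chrom[vi]
                or abs(tss[gi] - var_pos[vi]) > 1_200_000
            )
        ]
        return far[:k]

    # --- module latent factors: standardized Laplace (heavy-tailed) so that
    #     ICA has identifiable non-Gaussian sources
    raw_factors = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, cfg.n_modules))
    loadings = [
        rng.normal(0.8, 0.15, size=len(module_genes[mmod]))
        for mmod in range(cfg.n_modules)
    ]

    def _std_dosage(vi: int) -> np.ndarray:
        x = geno.dosages[:, vi]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        return (x - x.mean()) / (x.std() + 1e-12)

    used: set = set(local_set)
    for mg in module_genes:
        used.update(mg)
    for h, vi in enumerate(reg_idx):
        xs = _std_dosage(vi)
        effects: Dict[str, float] = {}
        if h == 0 and cfg.n_modules > 0:
            # hotspot 0 acts through module 0's latent factor: mix the
            # regulator genotype into the factor with the configured
            # variance share.  The residual's scale also depends on the
            # genotype (multiplicative regulatory noise), which keeps the
            # factor a single statistical source: a purely additive
            # genotype + independent-residual mixture would be split into
            # two components by ICA.
            a2 = cfg.module_regulator_r2
            a = np.sqrt(a2)
            span = xs.max() - xs.min()
            het = 1.0 + (xs - xs.min()) / span if span > 0 else np.ones_like(xs)
            resid = raw_factors[:, 0] * het
            resid /= resid.std() + 1e-12
            truth.module_trait_profile = resid.copy()
            f0 = a * xs + np.sqrt(1 - a2) * resid
            raw_factors[:, 0] = (f0 - f0.mean()) / (f0.std() + 1e-12)
            members = [
                gi for gi in module_genes[0]
                if gene_chrom[gi] != var_chrom[vi]
                or abs(tss[gi] - var_pos[vi]) > 1_200_000
            ]
            w_by_gene = dict(zip(module_genes[0], loadings[0]))
            for gi in members:
                effects[genes.loc[gi, "gene_id"]] = float(
                    cfg.module_sd * w_by_gene[gi] * a
                )
        else:
            members = far_genes(vi, cfg.genes_per_hotspot, used)
            for gi in members:
                r2 = cfg.hotspot_r2
                b = np.sqrt(r2 / (1 - r2)) * cfg.noise_sd
                b *= rng.choice([-1.0, 1.0])
                log_expr[gi] += b * xs
                effects[genes.loc[gi, "gene_id"]] = float(b)
                used.add(gi)
        truth.planted_hotspots.append(
            (geno.variants.loc[vi, "id"], [genes.loc[gi, "gene_id"] for gi in members], effects)
        )

    for mmod in range(cfg.n_modules):
        f = raw_factors[:, mmod]
        factors[:, mmod] = f
        for gi, w in zip(module_genes[mmod], loadings[mmod]):
            log_expr[gi] += cfg.module_sd * w * f
    truth.module_factors = factors

    # non-genetic variance = shared Gaussian background factors (broad
    # developmental/technical axes, as in real expression data) + iid
    # noise, partitioned so the per-gene total stays noise_sd^2 and the
    # planted-effect variance fractions above are unaffected
    if cfg.noise_sd > 0:
        share = cfg.background_share if cfg.n_background_factors > 0 else 0.0
        noise = np.sqrt(1.0 - share) * rng.standard_normal(log_expr.shape)
        if share > 0:
            bg = rng.standard_normal((cfg.n_background_factors, n))
            L = rng.standard_normal((n_genes, cfg.n_background_factors))
            L /= np.linalg.norm(L, axis=1, keepdims=True)
            noise += np.sqrt(share) * (L @ bg)
        log_expr += cfg.noise_sd * noise

    tpm = pd.DataFrame(
        np.exp(log_expr),
        index=genes["gene_id"],
        columns=geno.accessions["id"].to_numpy(),
    )
    return ExpressionMatrix(tpm=tpm, genes=genes), truth


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[TruthTable] = None,
) -> Tuple[PhenotypeTable, TruthTable]:
    """Two traits with genetic correlation ``trait_rg`` and heritabilities
    ``trait_h2``; per-variant effect pairs drawn from a bivariate normal.

    When a truth table with planted local eQTLs is supplied, the local
    eQTL variants of the first ``n_mediator_genes`` eGenes receive large
    shared effects, creating an expression-mediated variant→gene→trait
    chain for TWAS recovery tests.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    truth = TruthTable() if truth is None else truth
    n, m = geno.n_accessions, geno.n_variants
    h2 = cfg.trait_h2
    rg = cfg.trait_rg

    # mediator variants first, so the polygenic draw can exclude them
    med_idx: List[int] = []
    if truth.planted_local_eqtls and cfg.n_mediator_genes > 0:
        vid_to_idx = {v: i for i, v in enumerate(geno.variants["id"])}
        for vid, gid, _b in truth.planted_local_eqtls[: cfg.n_mediator_genes]:
            med_idx.append(vid_to_idx[vid])
            truth.mediator_genes.append(gid)

    n_causal = min(cfg.n_trait_causal, m - len(med_idx))
    pool = np.setdiff1d(np.arange(m), np.array(med_idx, dtype=int))
    causal = rng.choice(pool, size=n_causal, replace=False)
    # effects are on the standardized-dosage scale (the infinitesimal model
    # variance-component methods assume), so each locus contributes its
    # squared effect to the genetic variance regardless of allele frequency
    cov = np.array([[1.0, rg], [rg, 1.0]])
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_causal)

    if med_idx:
        # mediators alternate between a primary trait (large effect beta,
        # 12-17% of the trait's genetic variance: sized so the mediated
        # signal clears |Z|>=3 at n=300); the last one is pleiotropic with
        # a cross-trait effect gamma solved so that the expected genetic
        # correlation of the combined architecture equals trait_rg exactly.
        # A deterministic block (only overall signs random) keeps the
        # realized correlation concentrated at the planted value, which
        # five-ish independent large-effect draws would not.
        beta = np.sqrt(50.0)
        n_med = len(med_idx)
        block = np.zeros((n_med, 2))
        for j in range(n_med):
            block[j, j % 2] = beta
        o = 1 - (n_med - 1) % 2  # off-trait column of the last mediator
        a0 = float(np.sum(block[:, 0] ** 2))
        b0 = float(np.sum(block[:, 1] ** 2))
        p_var = float(n_causal)

        def _corr_gap(gamma: float) -> float:
            av = a0 + (gamma**2 if o == 0 else 0.0)
            bv = b0 + (gamma**2 if o == 1 else 0.0)
            return p_var * rg + beta * gamma - rg * np.sqrt(
                (p_var + av) * (p_var + bv)
            )

        gamma = 0.0
        if abs(rg) > 1e-12:
            from scipy.optimize import brentq

            hi = 10.0 * beta
            if _corr_gap(0.0) * _corr_gap(hi) < 0:
                gamma = brentq(_corr_gap, 0.0, hi)
        block[n_med - 1, o] = gamma
        signs = rng.choice([-1.0, 1.0], size=n_med)
        block *= signs[:, None]
        causal = np.concatenate([causal, np.array(med_idx, dtype=int)])
        eff = np.vstack([eff, block])

    X = geno.dosages[:, causal]
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
    g_raw = X @ eff  # n x 2
    g_std = np.zeros_like(g_raw)
    for t in range(2):
        sd = g_raw[:, t].std()
        g_std[:, t] = (g_raw[:, t] - g_raw[:, t].mean()) / sd if sd > 0 else 0.0

    y = np.zeros((n, 2))
    for t in range(2):
        e = rng.standard_normal(n)
        y[:, t] = np.sqrt(h2[t]) * g_std[:, t] + np.sqrt(1 - h2[t]) * e

    # module 0 (when planted) contributes a shared same-sign component to
    # both traits: the coexpression module is a common driver of the
    # pair.  The link uses the factor's non-genetic profile so the
    # planted polygenic genetic correlation is not inflated.
    if cfg.module_trait_r > 0:
        prof = truth.module_trait_profile
        if prof is None and truth.module_factors is not None:
            prof = truth.module_factors[:, 0]
        if prof is not None:
            prof = (prof - prof.mean()) / (prof.std() + 1e-12)
            r = cfg.module_trait_r
            for t in range(2):
                y[:, t] = np.sqrt(1 - r**2) * y[:, t] + r * prof

    acc = geno.accessions["id"].to_numpy()
    records = []
    for t, trait in enumerate(TRAITS):
        for year in (2019, 2020):
            vals = y[:, t] + rng.normal(0, 0.1, size=n)
            records.extend(zip(acc, [trait] * n, [year] * n, vals))
    rec = pd.DataFrame(records, columns=["accession_id", "trait", "year", "value"])
    blue = pd.DataFrame(y, index=pd.Index(acc, name="accession_id"), columns=list(TRAITS))

    for j, vi in enumerate(causal):
        truth.trait_variant_effects[geno.variants.loc[int(vi), "id"]] = (
            float(eff[j, 0]), float(eff[j, 1]),
        )
    truth.genetic_values = pd.DataFrame(
        g_std, index=pd.Index(acc, name="accession_id"), columns=list(TRAITS)
    )
    return PhenotypeTable(records=rec, blue=blue), truth


# ---------------------------------------------------------------------------
# domestication panels
# ---------------------------------------------------------------------------

PANELS = ("wild", "landrace", "cultivar")


def simulate_panels(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, GenotypeMatrix], TruthTable]:
    """Wild/landrace/cultivar panels sharing one variant set, with a planted
    sweep: one haplotype's frequency rises across panels over a designated
    region on chr1 and flanking diversity drops accordingly."""
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    truth = TruthTable()

    base = dataclasses.replace(
        cfg,
        n_accessions=cfg.panel_size,
        n_subpops=1,
        target_fst=0.0,
    )
    # shared ancestral frequencies/positions: draw one template panel layout
    template = simulate_genotypes(base, rng=np.random.default_rng(cfg.seed + 4))
    variants = template.variants

    chrom1 = variants[variants["chrom"] == "chr1"]
    center = cfg.chrom_length_bp // 2
    lo, hi = center - cfg.sweep_region_bp // 2, center + cfg.sweep_region_bp // 2
    region_idx = chrom1.index[(chrom1["pos"] >= lo) & (chrom1["pos"] <= hi)].to_numpy()
    if len(region_idx) == 0:
        raise ValueError("sweep region contains no variants; increase n_variants")
    swept_hap = template.haplotypes[0, region_idx].copy()

    # defining variants: up to 5 central sites of the region
    mid = len(region_idx) // 2
    span = region_idx[max(0, mid - 2): mid + 3]
    defining = variants.loc[span, "id"].tolist()

    panels: Dict[str, GenotypeMatrix] = {}
    for name, freq in zip(PANELS, cfg.sweep_freqs):
        sub_rng = np.random.default_rng(rng.integers(2**31 - 1))
        g = simulate_genotypes(base, rng=sub_rng)
        hap = g.haplotypes.copy()
        carrier = sub_rng.random(hap.shape[0]) < freq
        hap[np.ix_(carrier, region_idx)] = swept_hap
        dos = (hap[0::2] + hap[1::2]).astype(float)
        acc = g.accessions.copy()
        acc["id"] = [f"{name}{i:04d}" for i in range(len(acc))]
        panels[name] = GenotypeMatrix(dos, variants.copy(), acc, haplotypes=hap)

    truth.panel_swept_haplotype = {
        "region": ("chr1", int(lo), int(hi)),
        "defining_variants": defining,
        "haplotype": "".join(str(int(a)) for a in template.haplotypes[0, span]),
        "target_freqs": dict(zip(PANELS, cfg.sweep_freqs)),
    }
    return panels, truth


# ---------------------------------------------------------------------------
# full study + fixtures on disk
# ---------------------------------------------------------------------------

def _make_ocr(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Open-chromatin intervals: promoter-proximal for half the genes plus
    random background intervals (0-based half-open, BED convention)."""
    rows = []
    take = rng.random(len(genes)) < 0.5
    for _, g in genes[take].iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        rows.append((g["chrom"], max(0, tss - 1000), tss + 500))
    for _ in range(len(genes) // 4):
        c = rng.integers(1, cfg.n_chromosomes + 1)
        s = int(rng.integers(0, cfg.chrom_length_bp - 2000))
        rows.append((f"chr{c}", s, s + int(rng.integers(500, 2000))))
    ocr = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return ocr.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate genotypes, expression, traits and OCRs with one shared truth."""
    geno = simulate_genotypes(cfg)
    expr, truth = simulate_expression(geno, cfg)
    pheno, truth = simulate_traits(geno, cfg, truth=truth)
    ocr = _make_ocr(cfg, expr.genes, np.random.default_rng(cfg.seed + 5))
    return SimStudy(cfg, geno, expr, pheno, truth, ocr)


def _write_vcf(path: Path, geno: GenotypeMatrix, missing_frac: float, rng: np.random.Generator) -> None:
    n, m = geno.n_accessions, geno.n_variants
    trip = rng.random((n, m)) < missing_frac
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in geno.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accessions["id"])
            + "\n"
        )
        for j in range(m):
            v = geno.variants.iloc[j]
            cells = []
            for i in range(n):
                d = geno.dosages[i, j]
                if np.isnan(d):
                    cells.append("./.:.:.")
                    continue
                d = int(d)
                if trip[i, j]:
                    # values that trip the genotype-level filters
                    gq, dp = (10, 3) if d == 1 else (99, 1)
                else:
                    gq, dp = 99, 20
                cells.append(f"{gt_map[d]}:{gq}:{dp}")
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT:GQ:DP\t" + "\t".join(cells) + "\n"
            )


def _write_gff3(path: Path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tseedomics\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def write_fixture_set(outdir, cfg: SimConfig) -> Dict[str, Path]:
    """Write a complete on-disk study fixture: VCF (GT:GQ:DP), expression
    and phenotype TSVs, GFF3 gene models, OCR BED, truth TSVs and the three
    domestication panel VCFs.  Byte-identical for the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    paths: Dict[str, Path] = {}

    paths["vcf"] = outdir / "genotypes.vcf"
    _write_vcf(paths["vcf"], study.genotypes, cfg.missing_frac,
               np.random.default_rng(cfg.seed + 6))

    paths["expression"] = outdir / "expression.tsv"
    study.expression.tpm.round(6).to_csv(paths["expression"], sep="\t")

    paths["phenotypes"] = outdir / "phenotypes.tsv"
    rec = study.phenotypes.records.copy()
    blue = study.phenotypes.blue
    rec["blue"] = [
        round(blue.loc[a, t], 6) for a, t in zip(rec["accession_id"], rec["trait"])
    ]
    rec["value"] = rec["value"].round(6)
    rec.to_csv(paths["phenotypes"], sep="\t", index=False)

    paths["gff3"] = outdir / "genes.gff3"
    _write_gff3(paths["gff3"], study.expression.genes)

    paths["ocr"] = outdir / "ocr.bed"
    study.ocr.to_csv(paths["ocr"], sep="\t", header=False, index=False)

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        study.truth.planted_local_eqtls, columns=["variant", "gene", "effect"]
    ).to_csv(tdir / "local_eqtls.tsv", sep="\t", index=False)
    hot_rows = [
        (vid, gid, eff[gid])
        for vid, gids, eff in study.truth.planted_hotspots
        for gid in gids
    ]
    pd.DataFrame(hot_rows, columns=["regulator", "gene", "effect"]).to_csv(
        tdir / "hotspots.tsv", sep="\t", index=False
    )
    pd.Series(study.truth.module_membership, name="module").rename_axis("gene").to_csv(
        tdir / "modules.tsv", sep="\t"
    )
    pd.DataFrame(
        [(v, e[0], e[1]) for v, e in study.truth.trait_variant_effects.items()],
        columns=["variant", "effect_sw", "effect_oil"],
    ).to_csv(tdir / "trait_effects.tsv", sep="\t", index=False)
    paths["truth"] = tdir

    panels, ptruth = simulate_panels(cfg)
    for name, panel in panels.items():
        p = outdir / f"panel_{name}.vcf"
        _write_vcf(p, panel, 0.0, np.random.default_rng(cfg.seed + 7))
        paths[f"panel_{name}"] = p
    sw = ptruth.panel_swept_haplotype
    with open(tdir / "panel_sweep.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"region\t{sw['region'][0]}:{sw['region'][1]}-{sw['region'][2]}\n")
        fh.write(f"defining_variants\t{','.join(sw['defining_variants'])}\n")
        fh.write(f"haplotype\t{sw['haplotype']}\n")
        for pnl, f in sw["target_freqs"].items():
            fh.write(f"freq_{pnl}\t{f}\n")
    return paths
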