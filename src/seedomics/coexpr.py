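"""Coexpression modules by independent component analysis and their
trait/regulatory characterisation.

The expression matrix (genes x accessions, row-standardised) is decomposed
into k independent components, k chosen as the smallest PCA rank explaining
``var_cutoff`` percent of variance.  FastICA is run ``n_runs`` times from
seeded starts; components are matched across runs by absolute gene-weight
correlation, sign-aligned, and averaged, with the mean matched |r| reported
as a stability index.  A module is the set of genes whose |weight| exceeds
two standard deviations of that component's weights, and its per-accession
component score (the "eigengene") serves as a derived phenotype for GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

from .genotypes import GRM
from .mlm_assoc import Locus, clump, fit_mlm_loco
from .types import ExpressionMatrix, GenotypeMatrix, PhenotypeTable

__all__ = [
    "ICAModule",
    "run_ica",
    "ModuleTraitAssoc",
    "module_trait_correlation",
    "module_gwas",
    "module_distal_test",
    "partition_submodules",
    "gene_trait_correlations",
    "MotifEnrichment",
    "motif_enrichment",
]


@dataclass
class ICAModule:
    component: int
    gene_weights: pd.Series  # index = gene ids
    member_genes: List[str]
    eigen_expression: pd.Series  # index = accession ids
    stability: float = float("nan")


def _n_components_for_variance(X: np.ndarray, var_cutoff: float) -> int:
    """Smallest PCA rank whose cumulative explained variance reaches
    ``var_cutoff`` percent of the total."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = s**2
    cum = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(cum, var_cutoff / 100.0) + 1)


def run_ica(
    expr: ExpressionMatrix,
    var_cutoff: float = 70.0,
    max_iter: int = 200,
    n_runs: int = 15,
    seed: int = 0,
    membership_sd: float = 2.0,
    n_components: Optional[int] = None,
) -> List[ICAModule]:
    """Decompose the centered/standardised expression matrix into ICA
    coexpression modules (see module docstring for the procedure)."""
    genes = expr.tpm.index.to_list()
    acc = expr.tpm.columns.to_list()
    X = expr.tpm.to_numpy(dtype=float)
    if np.all(X >= 0):
        X = np.log1p(X)  # TPM scale -> log scale; already-centered input kept as is
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene rows; filter expression first")
    Xs = (X - mu) / sd  # genes x accessions

    k = n_components if n_components is not None else _n_components_for_variance(Xs.T, var_cutoff)
    if k >= min(len(genes), len(acc)):
        raise ValueError(f"requested {k} components for a {Xs.shape} matrix")

    # FastICA convention: rows of the input are observations.  Passing the
    # accessions x genes matrix makes sources the per-accession eigengene
    # profiles and the mixing matrix the gene-level weights.
    runs_W: List[np.ndarray] = []  # gene weights, genes x k
    runs_S: List[np.ndarray] = []  # eigengene scores, acc x k
    rng = np.random.default_rng(seed)
    for r in range(n_runs):
        ica = FastICA(
            n_components=k,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
            whiten="unit-variance",
            tol=1e-4,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = ica.fit_transform(Xs.T)  # acc x k
        runs_W.append(ica.mixing_)  # genes x k
        runs_S.append(S)

    # match components of later runs to the first run by |corr| of weights
    # (optimal one-to-one assignment), sign-align, average
    from scipy.optimize import linear_sum_assignment

    ref_W = runs_W[0]
    sum_W, sum_S = runs_W[0].copy(), runs_S[0].copy()
    match_r = np.ones(k)
    for r in range(1, n_runs):
        C = np.corrcoef(ref_W.T, runs_W[r].T)[:k, k:]
        rows, cols = linear_sum_assignment(-np.abs(C))
        for i, j in zip(rows, cols):
            sign = 1.0 if C[i, j] >= 0 else -1.0
            sum_W[:, i] += sign * runs_W[r][:, j]
            sum_S[:, i] += sign * runs_S[r][:, j]
            match_r[i] += abs(C[i, j])
    W = sum_W / n_runs
    S = sum_S / n_runs
    stability = match_r / n_runs

    modules: List[ICAModule] = []
    for c in range(k):
        w = W[:, c].copy()
        s = S[:, c].copy()
        if stats.skew(w) < 0:
            w, s = -w, -s
        cut = membership_sd * w.std()
        members = [genes[i] for i in np.flatnonzero(np.abs(w) > cut)]
        modules.append(
            ICAModule(
                component=c,
                gene_weights=pd.Series(w, index=genes),
                member_genes=members,
                eigen_expression=pd.Series(s, index=acc),
                stability=float(stability[c]),
            )
        )
    return modules


# ---------------------------------------------------------------------------
# module-trait association
# ---------------------------------------------------------------------------

@dataclass
class ModuleTraitAssoc:
    module: int
    trait: str
    r: float
    p: float
    q: float = float("nan")


def module_trait_correlation(
    modules: Sequence[ICAModule], pheno: PhenotypeTable
) -> List[ModuleTraitAssoc]:
    """Pearson correlation of each module eigengene with each trait BLUE,
    Benjamini-Hochberg corrected across modules x traits."""
    out: List[ModuleTraitAssoc] = []
    for mod in modules:
        shared = [a for a in mod.eigen_expression.index if a in pheno.blue.index]
        if len(shared) < 10:
            raise ValueError("fewer than 10 shared accessions")
        e = mod.eigen_expression.loc[shared].to_numpy()
        if np.std(e) == 0:
            continue
        for trait in pheno.blue.columns:
            y = pheno.blue.loc[shared, trait].to_numpy(dtype=float)
            r, p = stats.pearsonr(e, y)
            out.append(ModuleTraitAssoc(mod.component, trait, float(r), float(p)))
    if out:
        q = stats.false_discovery_control([a.p for a in out], method="bh")
        for a, qv in zip(out, q):
            a.q = float(qv)
    return out


def module_gwas(
    module: ICAModule,
    g: GenotypeMatrix,
    grms: Dict[str, GRM],
    threshold_p: float,
    clump_p2: float = 0.01,
    clump_r2: float = 0.5,
    clump_kb: float = 500,
) -> Tuple[List[Locus], pd.DataFrame]:
    """GWAS of a module eigengene (MLM-LOCO), clumped into loci at
    ``threshold_p``."""
    e = module.eigen_expression.loc[g.accessions["id"]].to_numpy(dtype=float)
    if np.std(e) == 0:
        raise ValueError("constant eigen-expression")
    res = fit_mlm_loco(g, e, grms)
    loci = clump(res, g, p1=threshold_p, p2=clump_p2, r2=clump_r2, kb=clump_kb)
    return loci, res


def module_distal_test(
    module_genes: Sequence[str],
    candidate_loci: Sequence[Tuple[str, int, int]],
    eqtl_records: Sequence,
    genome_genes: Sequence[str],
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> Tuple[pd.DataFrame, float]:
    """Permutation test for module-level distal regulation by candidate loci.

    Observed per locus = number of module genes with a distal eQTL lead in
    the locus interval.  Null: per permutation draw |module| random genes
    from the genome gene set and record the maximum such count across loci;
    threshold = (1 - alpha) quantile of the maxima; a locus passes when its
    observed count strictly exceeds the threshold.
    """
    genome_genes = list(genome_genes)
    if len(module_genes) > len(genome_genes):
        raise ValueError("module larger than the genome gene set")
    rng = np.random.default_rng(seed)
    # locus -> set of genes it distally regulates
    locus_genes: List[set] = []
    for chrom, start, end in candidate_loci:
        gs = {
            r.gene for r in eqtl_records
            if r.klass == "distal" and r.chrom == chrom and start <= r.pos <= end
        }
        locus_genes.append(gs)
    mod = set(module_genes)
    observed = np.array([len(gs & mod) for gs in locus_genes])

    null_max = np.zeros(n_perm)
    gg = np.array(genome_genes)
    for b in range(n_perm):
        draw = set(gg[rng.choice(len(gg), size=len(module_genes), replace=False)])
        null_max[b] = max((len(gs & draw) for gs in locus_genes), default=0)
    threshold = float(np.quantile(null_max, 1 - alpha))
    table = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in candidate_loci],
            "start": [s for _, s, _ in candidate_loci],
            "end": [e for _, _, e in candidate_loci],
            "observed": observed,
            "passes": observed > threshold,
        }
    )
    return table, threshold


# ---------------------------------------------------------------------------
# submodules and gene-level correlations
# ---------------------------------------------------------------------------

def partition_submodules(
    member_genes: Sequence[str],
    expr: ExpressionMatrix,
    corr_min: float = 0.3,
    min_size: int = 5,
    resolution: float = 1.0,
    seed: int = 0,
) -> Dict[str, int]:
    """Louvain partition of a module's gene-gene Spearman-correlation graph.

    Edges connect gene pairs with |rho| >= ``corr_min`` weighted by |rho|;
    communities smaller than ``min_size`` merge into the neighbouring
    community with the largest mean edge weight.  An empty graph yields a
    single community.
    """
    genes = [gid for gid in member_genes if gid in expr.tpm.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 member genes")
    X = np.log1p(expr.tpm.loc[genes].to_numpy(dtype=float))
    rho, _ = stats.spearmanr(X.T)
    rho = np.atleast_2d(rho)
    G = nx.Graph()
    G.add_nodes_from(range(len(genes)))
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if abs(rho[i, j]) >= corr_min:
                G.add_edge(i, j, weight=abs(rho[i, j]))
    if G.number_of_edges() == 0:
        return {gid: 0 for gid in genes}
    comms = list(
        nx.community.louvain_communities(G, weight="weight", resolution=resolution, seed=seed)
    )
    comms.sort(key=len, reverse=True)
    # merge undersized communities into the best-connected larger one
    big = [set(c) for c in comms if len(c) >= min_size]
    small = [set(c) for c in comms if len(c) < min_size]
    if not big:
        big, small = [set().union(*comms)], []
    for sc in small:
        best, best_w = 0, -1.0
        for bi, bc in enumerate(big):
            ws = [G[u][v]["weight"] for u in sc for v in bc if G.has_edge(u, v)]
            w = float(np.mean(ws)) if ws else 0.0
            if w > best_w:
                best, best_w = bi, w
        big[best] |= sc
    out: Dict[str, int] = {}
    for ci, comm in enumerate(big):
        for node in comm:
            out[genes[node]] = ci
    return out


def gene_trait_correlations(
    member_genes: Sequence[str],
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with each trait BLUE; the ``dual``
    column flags genes significant (p < ``p_max``) for both traits, and
    ``concordant`` records whether the two correlations share a sign."""
    acc = [a for a in expr.tpm.columns if a in pheno.blue.index]
    if len(acc) < 10:
        raise ValueError("fewer than 10 shared accessions")
    traits = list(pheno.blue.columns)
    rows = []
    for gid in member_genes:
        x = np.log1p(expr.tpm.loc[gid, acc].to_numpy(dtype=float))
        if np.std(x) == 0:
            rows.append([gid] + [np.nan] * (2 * len(traits)) + [False, False, True])
            continue
        rs, ps = [], []
        for trait in traits:
            y = pheno.blue.loc[acc, trait].to_numpy(dtype=float)
            r, p = stats.pearsonr(x, y)
            rs.append(r)
            ps.append(p)
        dual = all(p < p_max for p in ps)
        conc = np.sign(rs[0]) == np.sign(rs[1]) if len(rs) >= 2 else True
        rows.append([gid] + rs + ps + [dual, conc, False])
    cols = (
        ["gene"]
        + [f"r_{t}" for t in traits]
        + [f"p_{t}" for t in traits]
        + ["dual", "concordant", "excluded_constant"]
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# promoter motif enrichment (simplified log-odds scan + hypergeometric)
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    motif: str
    hits_in_module: int
    hits_in_background: int
    n_module: int
    n_background: int
    fold: float
    p: float
    q: float = float("nan")


def _pwm_hits(sequences: Dict[str, str], pssm, threshold: float) -> int:
    """Number of sequences with at least one log-odds hit on either strand."""
    hits = 0
    mlen = pssm.length
    for seq in sequences.values():
        if len(seq) < mlen:
            continue
        try:
            scores = pssm.calculate(seq.upper())
        except Exception:
            continue
        fwd = np.atleast_1d(np.asarray(scores, dtype=float))
        rev = np.atleast_1d(
            np.asarray(pssm.reverse_complement().calculate(seq.upper()), dtype=float)
        )
        allscores = np.concatenate([fwd, rev])
        allscores = allscores[~np.isnan(allscores)]
        if allscores.size and allscores.max() >= threshold:
            hits += 1
    return hits


def motif_enrichment(
    member_promoters: Dict[str, str],
    background_promoters: Dict[str, str],
    pwms,
    hit_fpr: float = 1e-4,
    hit_threshold: Optional[float] = None,
) -> List[MotifEnrichment]:
    """One-sided hypergeometric enrichment of PWM hits in module promoters.

    ``pwms`` is an iterable of Bio.motifs Motif objects (e.g. parsed from a
    minimal-MEME file).  A promoter is hit-bearing when its best log-odds
    score on either strand reaches the score whose false-positive rate under
    a 0-order background is ``hit_fpr`` (or an explicit ``hit_threshold``).
    Promoters shorter than the motif count as no-hit; q-values are
    Benjamini-Hochberg across motifs.
    """
    out: List[MotifEnrichment] = []
    n_mod, n_bg = len(member_promoters), len(background_promoters)
    for motif in pwms:
        pwm = motif.counts.normalize(pseudocounts=0.5)
        pssm = pwm.log_odds()
        if hit_threshold is None:
            from Bio.motifs.thresholds import ScoreDistribution

            sd = ScoreDistribution(precision=10**3, pssm=pssm,
                                   background={"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
            thr = sd.threshold_fpr(hit_fpr)
        else:
            thr = hit_threshold
        k_mod = _pwm_hits(member_promoters, pssm, thr)
        k_bg = _pwm_hits(background_promoters, pssm, thr)
        # module vs background universe (module assumed drawn from background)
        M = n_bg
        K = k_bg
        p = stats.hypergeom.sf(k_mod - 1, M, K, n_mod) if n_mod <= M else float("nan")
        fold = (k_mod / n_mod) / (k_bg / n_bg) if (n_mod and n_bg and k_bg) else float("inf") if k_mod else float("nan")
        out.append(
            MotifEnrichment(
                motif=str(motif.name),
                hits_in_module=k_mod,
                hits_in_background=k_bg,
                n_module=n_mod,
                n_background=n_bg,
                fold=float(fold),
                p=float(p),
            )
        )
    if out:
        q = stats.false_discovery_control([e.p for e in out], method="bh")
        for e, qv in zip(out, q):
            e.q = float(qv)
    return out
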