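"""Mixed-linear-model association with leave-one-chromosome-out kinship.

The workhorse is a single-random-effect MLM

    y = mu + x beta + g + e,   g ~ N(0, sg^2 K),  e ~ N(0, se^2 I),

fitted by eigendecomposition of the kinship K: variance components are
REML-estimated once per chromosome on the null model (profiled over the
heritability), then every variant on that chromosome gets a generalized
least-squares effect, standard error, signed t and p-value.  Also provides
an eigenvalue-based effective-number-of-tests threshold (simpleM style),
greedy LD-aware result clumping, bivariate REML genetic correlation, and
the cross-trait signed-t correlation summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GRM, compute_maf
from .types import GenotypeMatrix

__all__ = [
    "reml_null",
    "fit_mlm_loco",
    "effective_tests",
    "Locus",
    "clump",
    "VarCompEstimate",
    "bivariate_greml",
    "signed_t_correlation",
]


# ---------------------------------------------------------------------------
# univariate REML machinery
# ---------------------------------------------------------------------------

def _eig_grm(grm: GRM, ridge: float = 1e-8) -> Tuple[np.ndarray, np.ndarray]:
    A = grm.matrix
    d, U = np.linalg.eigh(A)
    if d.min() < 0:
        eps = -d.min() + ridge
        d = d + eps
    return d, U


def reml_null(y: np.ndarray, d: np.ndarray, U: np.ndarray) -> Tuple[float, float, float]:
    """REML fit of y = mu + g + e on an eigendecomposed kinship.

    Returns (h2, sigma_e^2, sigma_g^2) where variances are on the scale of
    V = sg^2 K + se^2 I.  The likelihood is profiled over h2 in (0, 1) and
    maximised by bounded scalar optimisation.
    """
    n = len(y)
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    def neg_reml(h2: float) -> float:
        v = h2 * d + (1 - h2)
        w = 1.0 / v
        s_oo = np.sum(w * ot * ot)
        s_oy = np.sum(w * ot * yt)
        mu = s_oy / s_oo
        resid = yt - mu * ot
        rss = np.sum(w * resid * resid)
        s2 = rss / (n - 1)
        return 0.5 * (np.sum(np.log(v)) + (n - 1) * np.log(s2) + np.log(s_oo))

    res = optimize.minimize_scalar(neg_reml, bounds=(1e-6, 1 - 1e-6), method="bounded")
    h2 = float(res.x)
    v = h2 * d + (1 - h2)
    w = 1.0 / v
    s_oo = np.sum(w * ot * ot)
    mu = np.sum(w * ot * yt) / s_oo
    resid = yt - mu * ot
    s2 = float(np.sum(w * resid * resid) / (n - 1))
    return h2, s2 * (1 - h2), s2 * h2


def _assoc_one_chrom(
    y: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    U: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised GLS effect/SE for all variants (columns of X) on one
    chromosome under the null-model variance components."""
    n = len(y)
    h2, se2, sg2 = reml_null(y, d, U)
    v = h2 * d + (1 - h2)
    w = 1.0 / v
    s2 = se2 + sg2  # total variance on the profiled scale

    yt = U.T @ y
    ot = U.T @ np.ones(n)
    Xt = U.T @ X

    s_oo = np.sum(w * ot * ot)
    s_oy = np.sum(w * ot * yt)
    Wx = Xt * w[:, None]
    s_ox = ot @ Wx
    s_xx = np.einsum("ij,ij->j", Xt, Wx)
    s_xy = yt @ Wx
    det = s_oo * s_xx - s_ox**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s_oo * s_xy - s_ox * s_oy) / det
        var_beta = s2 * s_oo / det
    se = np.sqrt(var_beta)
    return beta, se


def fit_mlm_loco(
    g: GenotypeMatrix,
    y: np.ndarray,
    grms: Dict[str, GRM],
    variant_idx: Optional[np.ndarray] = None,
    eig_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None,
) -> pd.DataFrame:
    """MLM association of every polymorphic variant against phenotype ``y``
    using, for each chromosome, the kinship built without that chromosome.

    ``grms`` maps chromosome name -> GRM excluding that chromosome; a single
    GRM under key ``"*"`` is used for all chromosomes (no LOCO).  Returns a
    DataFrame with variant id/chrom/pos/maf/beta/se/t/p; monomorphic
    variants are flagged with NaN statistics.
    """
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    n = g.n_accessions
    maf = compute_maf(g)
    out = g.variants[["id", "chrom", "pos"]].copy()
    out["maf"] = maf
    with np.errstate(invalid="ignore"):
        out["alt_freq"] = np.nanmean(g.dosages, axis=0) / 2.0
    beta = np.full(g.n_variants, np.nan)
    se = np.full(g.n_variants, np.nan)

    if eig_cache is None:
        eig_cache = {}

    sel = np.arange(g.n_variants) if variant_idx is None else np.asarray(variant_idx)
    selset = np.zeros(g.n_variants, dtype=bool)
    selset[sel] = True

    for chrom in pd.unique(g.variants["chrom"]):
        key = str(chrom) if str(chrom) in grms else "*"
        if key not in eig_cache:
            eig_cache[key] = _eig_grm(grms[key])
        d, U = eig_cache[key]
        idx = g.chrom_indices(chrom)
        idx = idx[selset[idx] & (maf[idx] > 0)]
        if len(idx) == 0:
            continue
        X = g.dosages[:, idx]
        X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
        b, s = _assoc_one_chrom(np.asarray(y, dtype=float), X, d, U)
        beta[idx] = b
        se[idx] = s

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = 2.0 * stats.norm.sf(np.abs(t))
    # numerical floor: p is in (0, 1]
    out["p"] = np.clip(out["p"], np.nextafter(0, 1), 1.0)
    return out


# ---------------------------------------------------------------------------
# effective number of tests (simpleM-style)
# ---------------------------------------------------------------------------

def effective_tests(
    g: GenotypeMatrix,
    window: int = 200,
    trace_frac: float = 0.995,
) -> Tuple[int, float]:
    """Eigenvalue-based effective number of independent tests.

    Per chromosome, in non-overlapping windows of ``window`` variants, count
    the leading eigenvalues of the dosage correlation matrix needed to reach
    ``trace_frac`` of its trace; M_eff is the sum over windows and the
    suggestive threshold is 0.05 / M_eff.
    """
    maf = compute_maf(g)
    m_eff = 0
    for chrom in pd.unique(g.variants["chrom"]):
        idx = g.chrom_indices(chrom)
        idx = idx[maf[idx] > 0]
        for start in range(0, len(idx), window):
            win = idx[start: start + window]
            if len(win) == 0:
                continue
            if len(win) == 1:
                m_eff += 1
                continue
            X = g.dosages[:, win]
            Xi = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
            sd = Xi.std(axis=0)
            Z = (Xi - Xi.mean(axis=0)) / np.where(sd == 0, 1, sd)
            C = (Z.T @ Z) / Z.shape[0]
            ev = np.linalg.eigvalsh(C)[::-1]
            ev = np.clip(ev, 0, None)
            cum = np.cumsum(ev) / ev.sum()
            m_eff += int(np.searchsorted(cum, trace_frac) + 1)
    return m_eff, 0.05 / m_eff


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    lead: str
    lead_idx: int
    chrom: str
    pos: int
    p: float
    members: List[str]
    member_idx: List[int]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.pos, self.pos)


def clump(
    results: pd.DataFrame,
    g: GenotypeMatrix,
    p1: float,
    p2: float = 0.01,
    r2: float = 0.5,
    kb: float = 500,
) -> List[Locus]:
    """Greedy LD-aware result clumping (PLINK ``--clump`` semantics).

    The most significant unassigned variant with p <= p1 becomes a lead;
    every unassigned variant with p <= p2, within ±kb on the same
    chromosome and with dosage r^2 >= ``r2`` against the lead joins its
    locus.  Ties on p break by (chrom, pos).
    """
    res = results.reset_index(drop=True)
    id_to_idx = {vid: i for i, vid in enumerate(g.variants["id"])}
    ps = res["p"].to_numpy()
    eligible = np.flatnonzero(~np.isnan(ps) & (ps <= p2))
    order = sorted(eligible, key=lambda i: (ps[i], res.loc[i, "chrom"], res.loc[i, "pos"]))
    assigned = np.zeros(len(res), dtype=bool)
    loci: List[Locus] = []
    chroms = res["chrom"].to_numpy()
    poss = res["pos"].to_numpy()

    Xi = np.where(np.isnan(g.dosages), np.nanmean(g.dosages, axis=0, keepdims=True), g.dosages)
    sd = Xi.std(axis=0)
    Z = (Xi - Xi.mean(axis=0)) / np.where(sd == 0, 1, sd)

    for i in order:
        if assigned[i] or ps[i] > p1:
            continue
        assigned[i] = True
        gi = id_to_idx[res.loc[i, "id"]]
        members, member_idx = [], []
        near = np.flatnonzero(
            ~assigned
            & (chroms == chroms[i])
            & (np.abs(poss - poss[i]) <= kb * 1000)
            & ~np.isnan(ps)
            & (ps <= p2)
        )
        if len(near):
            gj = np.array([id_to_idx[v] for v in res.loc[near, "id"]])
            rvec = (Z[:, gj].T @ Z[:, gi]) / Z.shape[0]
            hit = near[rvec**2 >= r2]
            assigned[hit] = True
            members = res.loc[hit, "id"].tolist()
            member_idx = [id_to_idx[v] for v in members]
        loci.append(
            Locus(
                lead=res.loc[i, "id"],
                lead_idx=gi,
                chrom=str(chroms[i]),
                pos=int(poss[i]),
                p=float(ps[i]),
                members=members,
                member_idx=member_idx,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# bivariate REML genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class VarCompEstimate:
    vg: Tuple[float, float]
    ve: Tuple[float, float]
    cov_g: float
    rg: float
    se_rg: float
    converged: bool
    loglik: float


def _chol_to_cov(theta: Sequence[float]) -> np.ndarray:
    l11, l21, l22 = theta
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    return L @ L.T


def bivariate_greml(
    y1: np.ndarray,
    y2: np.ndarray,
    grm: GRM,
    max_iter: int = 200,
) -> VarCompEstimate:
    """Bivariate REML on a single genome-wide kinship.

    The model stacks both traits with 2x2 genetic (Vg) and residual (Ve)
    covariance matrices; after rotating by the GRM eigenvectors the
    likelihood factorises over n independent 2x2 blocks, so each evaluation
    is O(n).  Vg and Ve are Cholesky-parameterised (positive semidefinite by
    construction) and maximised with L-BFGS-B; SE(rg) comes from the
    numerical Hessian via the delta method.
    """
    n = len(y1)
    if len(y2) != n:
        raise ValueError("traits must be measured on the same accessions")
    d, U = _eig_grm(grm)
    Y = np.column_stack([U.T @ np.asarray(y1, float), U.T @ np.asarray(y2, float)])
    a = U.T @ np.ones(n)  # rotated intercept design (per-block a_i * I2)

    def neg_reml(theta: np.ndarray) -> float:
        Vg = _chol_to_cov(theta[:3])
        Ve = _chol_to_cov(theta[3:])
        s11 = d * Vg[0, 0] + Ve[0, 0]
        s12 = d * Vg[0, 1] + Ve[0, 1]
        s22 = d * Vg[1, 1] + Ve[1, 1]
        det = s11 * s22 - s12**2
        if np.any(det <= 1e-300) or np.any(s11 <= 0):
            return 1e10
        i11, i12, i22 = s22 / det, -s12 / det, s11 / det
        a2 = a**2
        XtVX = np.array([
            [np.sum(a2 * i11), np.sum(a2 * i12)],
            [np.sum(a2 * i12), np.sum(a2 * i22)],
        ])
        XtVy = np.array([
            np.sum(a * (i11 * Y[:, 0] + i12 * Y[:, 1])),
            np.sum(a * (i12 * Y[:, 0] + i22 * Y[:, 1])),
        ])
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e10
        r1 = Y[:, 0] - a * beta[0]
        r2 = Y[:, 1] - a * beta[1]
        quad = np.sum(i11 * r1**2 + 2 * i12 * r1 * r2 + i22 * r2**2)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e10
        return 0.5 * (np.sum(np.log(det)) + logdet_x + quad)

    # multi-start: phenotypic halves with three genetic-correlation guesses
    v1, v2 = np.var(y1), np.var(y2)
    c12 = np.cov(y1, y2)[0, 1]
    r_ph = float(np.clip(c12 / np.sqrt(max(v1 * v2, 1e-300)), -0.9, 0.9))

    def chol_theta(v_a: float, v_b: float, r: float) -> list:
        l11 = np.sqrt(max(v_a, 1e-3))
        l21 = r * np.sqrt(max(v_b, 1e-3))
        l22 = np.sqrt(max(v_b * (1 - r**2), 1e-3))
        return [np.log(l11), l21, np.log(l22)]

    starts = [
        np.array(chol_theta(v1 / 2, v2 / 2, r0) + chol_theta(v1 / 2, v2 / 2, r0e))
        for r0, r0e in ((r_ph, r_ph), (0.0, 0.0), (0.8 * r_ph, 0.0))
    ]
    res = None
    for th0 in starts:
        cand = optimize.minimize(
            neg_reml, th0, method="Nelder-Mead",
            options={"maxiter": max_iter * 30, "xatol": 1e-7, "fatol": 1e-9},
        )
        cand = optimize.minimize(
            neg_reml, cand.x, method="Nelder-Mead",
            options={"maxiter": max_iter * 30, "xatol": 1e-7, "fatol": 1e-9},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    theta = res.x
    Vg = _chol_to_cov(theta[:3])
    Ve = _chol_to_cov(theta[3:])
    denom = np.sqrt(max(Vg[0, 0] * Vg[1, 1], 1e-300))
    rg = float(np.clip(Vg[0, 1] / denom, -1.0, 1.0))

    # delta-method SE of rg from the numerical Hessian of the REML surface
    se_rg = float("nan")
    try:
        eps = 1e-4
        k = len(theta)
        H = np.zeros((k, k))
        f0 = neg_reml(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.eye(k)[i] * eps
                ej = np.eye(k)[j] * eps
                H[i, j] = H[j, i] = (
                    neg_reml(theta + ei + ej) - neg_reml(theta + ei)
                    - neg_reml(theta + ej) + f0
                ) / eps**2
        cov_theta = np.linalg.pinv(H)

        def rg_of(th):
            Vgx = _chol_to_cov(th[:3])
            return Vgx[0, 1] / np.sqrt(max(Vgx[0, 0] * Vgx[1, 1], 1e-300))

        grad = np.array([
            (rg_of(theta + np.eye(k)[i] * eps) - rg_of(theta - np.eye(k)[i] * eps)) / (2 * eps)
            for i in range(k)
        ])
        var = grad @ cov_theta @ grad
        if var > 0:
            se_rg = float(np.sqrt(var))
    except np.linalg.LinAlgError:
        pass

    return VarCompEstimate(
        vg=(float(Vg[0, 0]), float(Vg[1, 1])),
        ve=(float(Ve[0, 0]), float(Ve[1, 1])),
        cov_g=float(Vg[0, 1]),
        rg=rg,
        se_rg=se_rg,
        converged=bool(res.success),
        loglik=float(-res.fun),
    )


# ---------------------------------------------------------------------------
# cross-trait signed-t correlation
# ---------------------------------------------------------------------------

def signed_t_correlation(res_a: pd.DataFrame, res_b: pd.DataFrame) -> Tuple[float, float]:
    """Pearson correlation (and p-value) of signed t statistics over the
    variants shared by two association scans."""
    merged = res_a[["id", "t"]].merge(res_b[["id", "t"]], on="id", suffixes=("_a", "_b"))
    merged = merged.dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared variants with finite t")
    r, p = stats.pearsonr(merged["t_a"], merged["t_b"])
    return float(r), float(p)
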