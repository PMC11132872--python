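"""Transcriptome-wide association: cis-heritability screening, expression
weight models, and the summary-statistic Z test.

Genes whose expression shows significant cis heritability (single-component
REML on a cis-variant kinship, likelihood-ratio test against zero) receive
expression weights over the variants in a +/- 500 kb window around the gene
span.  Four weight models are fitted (top1 indicator, ridge/BLUP, lasso,
elastic net) and the one with the best cross-validated predictive R^2 is
kept.  The TWAS statistic combines GWAS z-scores through the reference LD
matrix:

    Z = w' z / sqrt(w' R w)

with a small identity shrink on R for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold

from .types import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "cis_window_variants",
    "cis_h2",
    "ExpressionWeights",
    "fit_weights",
    "TWASResult",
    "twas_z",
    "call_candidates",
    "load_candidate_table",
]

CIS_WINDOW = 500_000


def cis_window_variants(
    g: GenotypeMatrix, gene_row: pd.Series, window: int = CIS_WINDOW
) -> np.ndarray:
    """Indices of variants within ``window`` bp of the gene span."""
    idx = g.chrom_indices(gene_row["chrom"])
    pos = g.variants["pos"].to_numpy()[idx]
    lo, hi = gene_row["start"] - window, gene_row["end"] + window
    return idx[(pos >= lo) & (pos <= hi)]


def _reml_loglik_profile(y: np.ndarray, d: np.ndarray, U: np.ndarray, h2: float) -> float:
    n = len(y)
    yt = U.T @ y
    ot = U.T @ np.ones(n)
    v = h2 * d + (1 - h2)
    w = 1.0 / v
    s_oo = np.sum(w * ot * ot)
    mu = np.sum(w * ot * yt) / s_oo
    resid = yt - mu * ot
    s2 = np.sum(w * resid * resid) / (n - 1)
    return -0.5 * (np.sum(np.log(v)) + (n - 1) * np.log(s2) + np.log(s_oo))


def cis_h2(
    gene_id: str,
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    window: int = CIS_WINDOW,
    min_cis: int = 30,
) -> Tuple[float, float]:
    """Cis heritability of a gene's expression and its LRT p-value.

    REML on the kinship built from cis-window variants; the likelihood
    ratio against h2 = 0 is referred to the 0.5*chi2(0) + 0.5*chi2(1)
    boundary mixture.
    """
    row = expr.genes.loc[gene_id]
    cis = cis_window_variants(g, row, window)
    if len(cis) < min_cis:
        raise ValueError(f"{gene_id}: only {len(cis)} cis variants (< {min_cis})")
    sub = g.take_variants(cis)
    Z = _standardize_dosages(sub.dosages)
    K = (Z @ Z.T) / Z.shape[1]
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0, None)
    y = expr.tpm.loc[gene_id].to_numpy(dtype=float)
    y = np.log1p(y)
    y = (y - y.mean()) / (y.std() + 1e-12)

    res = optimize.minimize_scalar(
        lambda h: -_reml_loglik_profile(y, d, U, h),
        bounds=(1e-6, 1 - 1e-6),
        method="bounded",
    )
    h2 = float(res.x)
    ll1 = _reml_loglik_profile(y, d, U, h2)
    ll0 = _reml_loglik_profile(y, d, U, 1e-9)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = 0.5 * stats.chi2.sf(lrt, df=1)
    return h2, float(p)


def _standardize_dosages(X: np.ndarray) -> np.ndarray:
    Xi = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    sd = Xi.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xi - Xi.mean(axis=0)) / sd


@dataclass
class ExpressionWeights:
    gene: str
    variant_idx: np.ndarray  # indices into the reference genotype matrix
    variant_ids: List[str]
    model: str
    weights: np.ndarray
    cv_r2: float
    cis_h2: float
    cis_h2_p: float
    all_cv_r2: Dict[str, float] = field(default_factory=dict)


def _cv_r2(pred: np.ndarray, y: np.ndarray) -> float:
    """Out-of-fold predictive R^2 (1 - SSE/SST)."""
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return float("-inf")
    return float(1.0 - np.sum((y - pred) ** 2) / sst)


def fit_weights(
    gene_id: str,
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    models: Sequence[str] = ("top1", "blup", "lasso", "enet"),
    k_folds: int = 5,
    seed: int = 0,
    window: int = CIS_WINDOW,
    h2: Optional[float] = None,
    h2_p: Optional[float] = None,
) -> Optional[ExpressionWeights]:
    """Fit expression weight models on the cis window and keep the best by
    cross-validated R^2.  Returns None (gene dropped) when no model predicts
    better than the mean."""
    row = expr.genes.loc[gene_id]
    cis = cis_window_variants(g, row, window)
    if len(cis) == 0:
        return None
    X = _standardize_dosages(g.dosages[:, cis])
    y = np.log1p(expr.tpm.loc[gene_id].to_numpy(dtype=float))
    y = (y - y.mean()) / (y.std() + 1e-12)
    n, m = X.shape
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)

    def fit_model(name: str, Xtr, ytr):
        if name == "top1":
            r = Xtr.T @ ytr / len(ytr)
            w = np.zeros(m)
            j = int(np.argmax(np.abs(r)))
            w[j] = r[j]
            return w
        if name == "blup":
            hh = h2 if h2 is not None else 0.2
            lam = m * (1 - hh) / max(hh, 1e-3)
            ridge = Ridge(alpha=lam, fit_intercept=False)
            ridge.fit(Xtr, ytr)
            return ridge.coef_
        if name == "lasso":
            las = LassoCV(cv=3, random_state=seed, alphas=20, max_iter=2000)
            las.fit(Xtr, ytr)
            return las.coef_
        if name == "enet":
            en = ElasticNetCV(l1_ratio=0.5, cv=3, random_state=seed, alphas=20, max_iter=2000)
            en.fit(Xtr, ytr)
            return en.coef_
        raise ValueError(name)

    cv_scores: Dict[str, float] = {}
    for name in models:
        pred = np.zeros(n)
        for tr, te in kf.split(X):
            w = fit_model(name, X[tr], y[tr])
            pred[te] = X[te] @ w
        cv_scores[name] = _cv_r2(pred, y)

    best = max(cv_scores, key=cv_scores.get)
    if cv_scores[best] <= 0:
        return None
    w = fit_model(best, X, y)
    return ExpressionWeights(
        gene=gene_id,
        variant_idx=cis,
        variant_ids=g.variants.loc[cis, "id"].tolist(),
        model=best,
        weights=w,
        cv_r2=cv_scores[best],
        cis_h2=h2 if h2 is not None else float("nan"),
        cis_h2_p=h2_p if h2_p is not None else float("nan"),
        all_cv_r2=cv_scores,
    )


@dataclass
class TWASResult:
    gene: str
    z: float
    p: float
    lead_gwas_variant: str
    lead_gwas_p: float


def twas_z(
    weights: ExpressionWeights,
    gwas: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    shrink: float = 0.1,
) -> Optional[TWASResult]:
    """TWAS Z from expression weights and GWAS summary statistics.

    Z = w'z / sqrt(w' R w) with R the dosage correlation among weighted
    variants in the reference panel, shrunk as (1 - shrink) R + shrink I
    (diagonal stays 1, so a single-indicator weight reproduces that
    variant's GWAS z exactly).  Variants missing from the GWAS get weight
    zero; a non-positive quadratic form drops the gene.
    """
    nz = np.flatnonzero(weights.weights != 0)
    if len(nz) == 0:
        return None
    ids = [weights.variant_ids[i] for i in nz]
    w = weights.weights[nz].astype(float)
    gz = gwas.set_index("id")
    zvec = np.zeros(len(ids))
    for k, vid in enumerate(ids):
        if vid in gz.index and np.isfinite(gz.loc[vid, "t"]):
            zvec[k] = gz.loc[vid, "t"]
        else:
            w[k] = 0.0
    if np.all(w == 0):
        return None
    X = _standardize_dosages(ld_ref.dosages[:, weights.variant_idx[nz]])
    R = (X.T @ X) / X.shape[0]
    R = (1 - shrink) * R + shrink * np.eye(len(w))
    denom = float(w @ R @ w)
    if denom <= 0:
        return None
    z = float(w @ zvec / np.sqrt(denom))
    # lead GWAS variant in the cis window
    win = gwas[gwas["id"].isin(weights.variant_ids)].dropna(subset=["p"])
    if len(win):
        lead = win.loc[win["p"].idxmin()]
        lead_id, lead_p = str(lead["id"]), float(lead["p"])
    else:
        lead_id, lead_p = "", float("nan")
    return TWASResult(
        gene=weights.gene,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        lead_gwas_variant=lead_id,
        lead_gwas_p=lead_p,
    )


def call_candidates(
    twas_results: pd.DataFrame,
    egwas_z: Optional[Dict[str, float]] = None,
    z_min: float = 3.0,
    joint: bool = True,
) -> pd.DataFrame:
    """Candidate genes with |TWAS Z| >= ``z_min`` (and, when ``egwas_z`` is
    given and ``joint``, |eGWAS Z| >= ``z_min`` as well).

    ``twas_results`` needs columns ``trait, gene, twas_z`` (extra columns
    pass through), one row per (trait, gene).
    """
    out = twas_results[np.abs(twas_results["twas_z"]) >= z_min].copy()
    if egwas_z is not None:
        ez = out["gene"].map(lambda gid: abs(egwas_z.get(gid, np.nan)))
        if joint:
            out = out[ez >= z_min]
        else:
            pass  # alternative reading: TWAS alone suffices
    return out.reset_index(drop=True)


def load_candidate_table() -> pd.DataFrame:
    """Packaged example: a published soybean seed-weight / oil-content TWAS
    summary table (trait, gene, lead GWAS SNP and p, TWAS Z and p)."""
    with resources.files("seedomics.data").joinpath("twas_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
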