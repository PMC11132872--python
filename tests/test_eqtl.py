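"""eQTL mapping, hotspot and enrichment permutation machinery, checked
against literal re-implementations sharing the same random seed."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedomics.eqtl import (
    EQTLRecord,
    classify_local_distal,
    detect_hotspots,
    explained_variance,
    filter_expression,
    map_eqtls,
    ocr_enrichment,
    quantile_normalize,
    summarize_eqtl_classes,
)
from seedomics.genotypes import GRM
from seedomics.types import ExpressionMatrix

from conftest import make_geno


def _expr(tpm_rows, gene_rows):
    tpm = pd.DataFrame(
        tpm_rows, index=pd.Index([g["gene_id"] for g in gene_rows], name="gene")
    )
    tpm.columns = [f"a{i}" for i in range(tpm.shape[1])]
    return ExpressionMatrix(tpm=tpm, genes=pd.DataFrame(gene_rows))


def _gene(gid, chrom="chr1", start=1000, end=2000, strand="+"):
    return {"gene_id": gid, "chrom": chrom, "start": start, "end": end, "strand": strand}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_filter_expression_rules():
    n = 20
    rng = np.random.default_rng(0)
    high_var = 6 + 40 * rng.random(n)           # expressed, fold > 2
    low = np.full(n, 1.0)                        # never reaches tpm_min
    flat = np.full(n, 50.0); flat[0] = 55.0      # expressed but fold < 2
    zero_q05 = np.zeros(n); zero_q05[-3:] = 80.0  # q05 == 0 -> fold passes
    ex = _expr(
        [high_var, low, flat, zero_q05],
        [_gene("gA"), _gene("gB"), _gene("gC"), _gene("gD")],
    )
    kept = filter_expression(ex)
    assert set(kept.tpm.index) == {"gA", "gD"}
    only_low = _expr([low], [_gene("gB")])
    with pytest.raises(ValueError, match="no genes pass"):
        filter_expression(only_low)


def test_quantile_normalize_matches_rank_formula():
    v = np.array([3.0, 1.0, 2.0, 2.0, 10.0])
    out = quantile_normalize(v)
    ranks = stats.rankdata(v)  # ties -> average rank
    expect = stats.norm.ppf((ranks - 0.5) / 5)
    assert np.allclose(out, expect)
    assert out[2] == out[3]  # tied inputs stay tied
    with pytest.raises(ValueError, match="constant"):
        quantile_normalize(np.ones(10))
    with pytest.raises(ValueError, match="at least 3"):
        quantile_normalize(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# mapping on a planted signal
# ---------------------------------------------------------------------------

def test_map_eqtls_finds_planted_local_and_skips_noise():
    rng = np.random.default_rng(1)
    n, m = 200, 30
    D = rng.integers(0, 3, size=(n, m)).astype(float)
    x = D[:, 12]
    for j in (10, 11, 13, 14):  # LD proxies of the causal variant
        flip = rng.random(n) < 0.05
        D[:, j] = np.where(flip, rng.integers(0, 3, size=n), x)
    g = make_geno(D, spacing=5000)
    causal_pos = int(g.variants.loc[12, "pos"])
    tpm_signal = 10 + 2 * x + 0.5 * rng.standard_normal(n)
    tpm_noise = 10 + rng.standard_normal(n)
    ex = _expr(
        [tpm_signal, tpm_noise],
        [
            _gene("gSig", start=causal_pos - 2000, end=causal_pos + 2000),
            _gene("gNull", start=1000, end=2000),
        ],
    )
    grms = {"*": GRM(matrix=np.eye(n), variant_idx=np.arange(m))}
    records = map_eqtls(g, ex, grms)
    assert {r.gene for r in records} == {"gSig"}
    rec = records[0]
    assert rec.lead_idx in {10, 11, 12, 13, 14}
    assert rec.n_proxies >= 2
    classify_local_distal(records, ex.genes)
    assert rec.klass == "local"
    r2 = explained_variance(rec, g, ex)
    assert r2 > 0.5 and rec.r2_explained == r2


def test_explained_variance_rejects_monomorphic_lead():
    g = make_geno(np.column_stack([np.ones(30), np.arange(30) % 3]).astype(float))
    ex = _expr([10 + np.arange(30.0)], [_gene("g1")])
    rec = EQTLRecord(gene="g1", lead="v0", lead_idx=0, chrom="chr1", pos=1000,
                     p=1e-9, n_proxies=3)
    with pytest.raises(ValueError, match="monomorphic"):
        explained_variance(rec, g, ex)


def test_classify_local_distal_boundaries():
    genes = pd.DataFrame([
        _gene("g1", chrom="chr1", start=5_000_000, end=5_010_000),
    ])
    mk = lambda chrom, pos: EQTLRecord(
        gene="g1", lead="v", lead_idx=0, chrom=chrom, pos=pos, p=1e-8, n_proxies=2
    )
    recs = [
        mk("chr1", 5_005_000),   # inside the gene span
        mk("chr1", 6_010_000),   # exactly 1 Mb from the end: boundary local
        mk("chr1", 6_010_001),   # one bp beyond: distal
        mk("chr2", 5_005_000),   # other chromosome: distal
    ]
    classify_local_distal(recs, genes)
    assert [r.klass for r in recs] == ["local", "local", "distal", "distal"]
    with pytest.raises(KeyError, match="unknown gene"):
        classify_local_distal(
            [EQTLRecord(gene="nope", lead="v", lead_idx=0, chrom="chr1", pos=1,
                        p=1e-8, n_proxies=2)],
            genes,
        )


# ---------------------------------------------------------------------------
# hotspot permutation threshold vs shared-seed oracle
# ---------------------------------------------------------------------------

def _count_windows(pos, codes, length, window, step):
    """Brute-force distinct-gene counts per window (both ends inclusive)."""
    starts = np.arange(0, max(length - window, 0) + 1, step)
    counts = []
    for s in starts:
        inwin = (pos >= s) & (pos <= s + window)
        counts.append(len(set(codes[inwin])))
    return starts, np.array(counts)


def test_detect_hotspots_matches_exhaustive_oracle():
    genome = {"chr1": 10_000_000, "chr2": 10_000_000}
    window, step, n_perm, seed, alpha = 1_000_000, 100_000, 200, 3, 0.05
    rng0 = np.random.default_rng(99)
    records = []
    # a dense cluster of 30 distal eGenes near 5 Mb on chr1
    for i in range(30):
        records.append(EQTLRecord(
            gene=f"g{i}", lead=f"v{i}", lead_idx=i, chrom="chr1",
            pos=int(5_000_000 + rng0.integers(0, 400_000)), p=1e-9,
            n_proxies=3, klass="distal",
        ))
    # sparse background on both chromosomes
    for i in range(30, 40):
        records.append(EQTLRecord(
            gene=f"g{i}", lead=f"v{i}", lead_idx=i,
            chrom="chr2" if i % 2 else "chr1",
            pos=int(rng0.integers(0, 10_000_000)), p=1e-9,
            n_proxies=3, klass="distal",
        ))
    # a local record must be ignored entirely
    records.append(EQTLRecord(gene="gL", lead="vL", lead_idx=99, chrom="chr1",
                              pos=5_100_000, p=1e-9, n_proxies=3, klass="local"))

    hotspots, threshold = detect_hotspots(
        records, genome, window=window, step=step,
        n_perm=n_perm, alpha=alpha, seed=seed,
    )

    # oracle: replay the null with the same seed and draw order
    distal = [r for r in records if r.klass == "distal"]
    genes_u = {gid: i for i, gid in enumerate(sorted({r.gene for r in distal}))}
    by_chrom = {
        chrom: (
            np.array([r.pos for r in distal if r.chrom == chrom], dtype=float),
            np.array([genes_u[r.gene] for r in distal if r.chrom == chrom]),
        )
        for chrom in genome
    }
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        best = 0
        for chrom, length in genome.items():
            pos, codes = by_chrom[chrom]
            rpos = rng.uniform(0, length, size=len(pos))
            _, counts = _count_windows(rpos, codes, length, window, step)
            best = max(best, counts.max())
        null_max[b] = best
    assert threshold == pytest.approx(float(np.quantile(null_max, 1 - alpha)))

    # the planted cluster is flagged and fully captured; nothing on chr2
    assert len(hotspots) == 1
    hs = hotspots[0]
    assert hs.chrom == "chr1" and hs.passes
    assert hs.start <= 5_000_000 and hs.end >= 5_400_000
    cluster = {f"g{i}" for i in range(30)}
    assert cluster <= set(hs.egenes)
    assert "gL" not in hs.egenes

    # observed window counts agree with the brute-force counter
    pos, codes = by_chrom["chr1"]
    starts, counts = _count_windows(pos, codes, genome["chr1"], window, step)
    assert counts.max() >= 30
    flagged = starts[counts > threshold]
    assert hs.start == int(flagged.min())


# ---------------------------------------------------------------------------
# OCR enrichment vs shared-seed oracle
# ---------------------------------------------------------------------------

def _overlap_oracle(leads, intervals):
    total = 0
    for r in leads:
        p0 = r.pos - 1  # 1-based position -> 0-based BED coordinate
        for _, row in intervals.iterrows():
            if row["chrom"] == r.chrom and row["start"] <= p0 < row["end"]:
                total += 1
                break
    return total


def test_ocr_enrichment_matches_exhaustive_oracle():
    genome = {"chr1": 2_000_000}
    leads = [
        EQTLRecord(gene=f"g{i}", lead=f"v{i}", lead_idx=i, chrom="chr1",
                   pos=100_001 + 50_000 * i, p=1e-9, n_proxies=2, klass="local")
        for i in range(12)
    ]
    # intervals covering every lead exactly
    ocr = pd.DataFrame({
        "chrom": ["chr1"] * 12,
        "start": [100_000 + 50_000 * i for i in range(12)],
        "end": [100_200 + 50_000 * i for i in range(12)],
    })
    n_perm, seed = 99, 11
    obs, null_mean, ci, p = ocr_enrichment(leads, ocr, genome, n_perm=n_perm, seed=seed)
    assert obs == 12 == _overlap_oracle(leads, ocr)

    # replay the permutation null with the same seed and draw order
    rng = np.random.default_rng(seed)
    lengths = (ocr["end"] - ocr["start"]).to_numpy()
    null = np.empty(n_perm)
    for b in range(n_perm):
        starts = np.array([rng.integers(0, genome["chr1"] - L) for L in lengths])
        perm = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + lengths})
        null[b] = _overlap_oracle(leads, perm)
    assert null_mean == pytest.approx(null.mean())
    assert p == pytest.approx((1 + np.sum(null >= obs)) / (n_perm + 1))
    assert ci == (pytest.approx(np.quantile(null, 0.025)),
                  pytest.approx(np.quantile(null, 0.975)))
    assert obs > null_mean and p < 0.05

    bad = ocr.copy()
    bad.loc[0, "end"] = 3_000_000
    with pytest.raises(ValueError, match="beyond chromosome end"):
        ocr_enrichment(leads, bad, genome, n_perm=5, seed=0)


# ---------------------------------------------------------------------------
# class bookkeeping
# ---------------------------------------------------------------------------

def test_summarize_eqtl_classes_counts_and_rounding():
    mk = lambda gene, klass: EQTLRecord(
        gene=gene, lead="v", lead_idx=0, chrom="chr1", pos=1, p=1e-8,
        n_proxies=2, klass=klass,
    )
    # 8 eQTLs over 6 genes: gA local-only, gB local-only, gC..gE distal-only,
    # gF both; 1 local of 8 -> 12.5% must round half away from zero to 13
    recs = [
        mk("gA", "local"),
        mk("gB", "local"),
        mk("gC", "distal"), mk("gD", "distal"), mk("gE", "distal"),
        mk("gF", "local"), mk("gF", "distal"),
        mk("gE", "distal"),
    ]
    s = summarize_eqtl_classes(recs)
    assert s["n_eqtls"] == 8
    assert s["n_local"] == 3 and s["n_distal"] == 5
    assert s["pct_local"] == 38 and s["pct_distal"] == 63  # 37.5 / 62.5
    assert s["n_egenes"] == 6
    assert s["n_local_only"] == 2
    assert s["n_distal_only"] == 3
    assert s["n_both"] == 1
    assert s["pct_local_only"] == 33
    assert s["pct_distal_only"] == 50
    assert s["pct_both"] == 17
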