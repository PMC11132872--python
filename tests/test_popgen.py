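"""Diversity and differentiation statistics against hand-evaluated
formulas on small counts."""
import numpy as np
import pandas as pd
import pytest

from seedomics.popgen import (
    haplotype_spectrum,
    pi_ratio_scan,
    site_pi,
    windowed_fst,
    windowed_pi,
)

from conftest import make_geno


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def test_site_pi_hand_formula():
    # site 0: 6 accessions, alt count 3 of 12 alleles -> p = 0.25, n = 12
    # site 1: one missing -> n = 10, alt count 4 -> p = 0.4
    # site 2: monomorphic -> pi = 0
    d = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 1.0, 2.0],
        [0.0, 0.0, 2.0],
        [2.0, 2.0, 2.0],
        [0.0, 0.0, 2.0],
        [0.0, np.nan, 2.0],
    ])
    pi = site_pi(d)
    assert pi[0] == pytest.approx(2 * 0.25 * 0.75 * 12 / 11)
    assert pi[1] == pytest.approx(2 * 0.4 * 0.6 * 10 / 9)
    assert pi[2] == pytest.approx(0.0)


def test_windowed_pi_sums_sites_over_window_length():
    d = np.array([
        [0.0, 2.0, 1.0],
        [2.0, 2.0, 1.0],
        [0.0, 2.0, 0.0],
        [2.0, 2.0, 0.0],
    ])
    # positions 1000, 2000, 3000; windows of 2500 bp stepping 2500
    g = make_geno(d, start_pos=1000, spacing=1000)
    out = windowed_pi(g, {"chr1": 5000}, window_bp=2500, step_bp=2500)
    spi = site_pi(d)
    # window [0, 2500] holds sites at 1000 and 2000; [2500, 5000] the site at 3000
    assert out.loc[0, "pi"] == pytest.approx((spi[0] + spi[1]) / 2500)
    assert out.loc[1, "pi"] == pytest.approx(spi[2] / 2500)
    assert not out["no_sites"].any()
    empty = windowed_pi(g, {"chr1": 5000, "chr9": 3000}, window_bp=2500, step_bp=2500)
    assert empty[empty["chrom"] == "chr9"]["no_sites"].all()
    with pytest.raises(ValueError, match="at least 2"):
        windowed_pi(g.take_accessions([0]), {"chr1": 5000})


def test_pi_ratio_scan_thresholds_and_caps():
    key = {"chrom": ["chr1"] * 6, "start": np.arange(6) * 100,
           "end": np.arange(6) * 100 + 100}
    pa = pd.DataFrame({**key, "pi": [1.0, 2.0, 30.0, 0.0, 5.0, 0.0]})
    pb = pd.DataFrame({**key, "pi": [1.0, 1.0, 1.0, 0.0, 0.0, 2.0]})
    out = pi_ratio_scan(pa, pb, top_frac=0.25)
    assert np.isnan(out.loc[3, "ratio"])                # 0/0 excluded
    assert out.loc[4, "ratio"] == pytest.approx(30.0)   # 5/0 capped at max finite
    assert bool(out.loc[4, "capped"])
    finite = np.array([1.0, 2.0, 30.0, 30.0, 0.0])
    thr = np.quantile(finite, 0.75)
    assert out.attrs["threshold"] == pytest.approx(thr)
    assert out["flagged"].tolist() == [
        bool(np.isfinite(r) and r >= thr) for r in out["ratio"]
    ]
    bad = pb.copy()
    bad.loc[0, "start"] = 7
    with pytest.raises(ValueError, match="tilings differ"):
        pi_ratio_scan(pa, bad)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_single_site(n1, p1, h1, n2, p2, h2):
    """Hand-coded Weir & Cockerham (1984) two-population components."""
    r = 2.0
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
    return a, b, c


def test_windowed_fst_matches_hand_evaluation():
    # panel A: 10 diploids, 8 hom-alt + 2 hom-ref -> p = 0.8, no hets
    # panel B: 10 diploids, 2 hom-alt + 8 hom-ref -> p = 0.2, no hets
    da = np.array([[2.0]] * 8 + [[0.0]] * 2)
    db = np.array([[2.0]] * 2 + [[0.0]] * 8)
    ga, gb = make_geno(da), make_geno(db)
    out = windowed_fst(ga, gb, {"chr1": 2000}, window_bp=2000, step_bp=2000)
    a, b, c = _wc_single_site(10, 0.8, 0.0, 10, 0.2, 0.0)
    assert out.loc[0, "fst"] == pytest.approx(a / (a + b + c), abs=1e-10)
    assert not out.loc[0, "undefined"]

    # with heterozygotes the c component enters: 4 hets in panel A
    da2 = np.array([[2.0]] * 6 + [[1.0]] * 4)        # p = 0.8, h = 0.4
    db2 = np.array([[2.0]] * 2 + [[0.0]] * 8)
    out2 = windowed_fst(make_geno(da2), make_geno(db2), {"chr1": 2000},
                        window_bp=2000, step_bp=2000)
    a2, b2, c2 = _wc_single_site(10, 0.8, 0.4, 10, 0.2, 0.0)
    assert out2.loc[0, "fst"] == pytest.approx(a2 / (a2 + b2 + c2), abs=1e-10)

    # symmetry in the panel order
    swapped = windowed_fst(gb, ga, {"chr1": 2000}, window_bp=2000, step_bp=2000)
    assert swapped.loc[0, "fst"] == pytest.approx(out.loc[0, "fst"], abs=1e-12)

    # identical panels: no divergence signal, near-zero (can be negative)
    same = windowed_fst(ga, ga, {"chr1": 2000}, window_bp=2000, step_bp=2000)
    assert same.loc[0, "fst"] < 0.05


def test_windowed_fst_input_validation():
    da = np.array([[2.0]] * 4)
    g1 = make_geno(da)
    with pytest.raises(ValueError, match="at least 2"):
        windowed_fst(g1.take_accessions([0]), g1, {"chr1": 2000})
    g2 = make_geno(da)
    g2.variants.loc[0, "id"] = "other"
    with pytest.raises(ValueError, match="share one variant set"):
        windowed_fst(g1, g2, {"chr1": 2000})


# ---------------------------------------------------------------------------
# haplotype spectra
# ---------------------------------------------------------------------------

def test_haplotype_spectrum_phased_and_unphased():
    # phased panel: 3 accessions = 6 haplotypes over 2 defining variants
    H = np.array([
        [1, 1],
        [1, 1],
        [1, 1],
        [0, 0],
        [0, 0],
        [1, 0],
    ], dtype=float)
    dos = H[0::2] + H[1::2]
    phased = make_geno(dos, haplotypes=H)
    # unphased panel: hom rows countable, any het row excluded
    unphased = make_geno(np.array([
        [2.0, 2.0],   # -> "11" twice
        [0.0, 0.0],   # -> "00" twice
        [1.0, 2.0],   # het -> excluded
    ]))
    spec = haplotype_spectrum({"wild": phased, "landrace": unphased}, ["v0", "v1"])
    assert spec.haplotypes["Hap1"] == "11"  # pooled count 3 + 2 = 5
    assert spec.counts.loc["Hap1", "wild"] == 3
    assert spec.counts.loc["Hap1", "landrace"] == 2
    assert spec.frequencies.loc["Hap1", "wild"] == pytest.approx(3 / 6)
    assert spec.frequencies.loc["Hap1", "landrace"] == pytest.approx(2 / 4)
    # the het accession contributes nothing to the unphased denominator
    assert spec.counts["landrace"].sum() == 4
    assert spec.defining_variants == ["v0", "v1"]

    with pytest.raises(ValueError, match="missing from panel"):
        haplotype_spectrum({"wild": phased}, ["v0", "nope"])


def test_haplotype_spectrum_pools_rare_into_other():
    rng = np.random.default_rng(0)
    H = rng.integers(0, 2, size=(40, 3)).astype(float)
    g = make_geno(H[0::2] + H[1::2], haplotypes=H)
    spec = haplotype_spectrum({"p": g}, ["v0", "v1", "v2"], max_haplotypes=2)
    assert list(spec.counts.index) == ["Hap1", "Hap2", "other"]
    assert spec.counts["p"].sum() == 40
    assert spec.frequencies["p"].sum() == pytest.approx(1.0)
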