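"""ICA coexpression modules, eigengene associations, and the module-level
permutation test, verified against planted structure and replayed nulls."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedomics.coexpr import (
    ICAModule,
    gene_trait_correlations,
    module_distal_test,
    module_gwas,
    module_trait_correlation,
    motif_enrichment,
    partition_submodules,
    run_ica,
)
from seedomics.eqtl import EQTLRecord
from seedomics.genotypes import GRM
from seedomics.types import ExpressionMatrix, PhenotypeTable

from conftest import make_geno


def _expr_matrix(X, gene_ids, acc_ids):
    tpm = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene"), columns=acc_ids)
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": "chr1",
        "start": 1000 + 1000 * np.arange(len(gene_ids)),
        "end": 1500 + 1000 * np.arange(len(gene_ids)),
        "strand": "+",
    })
    return ExpressionMatrix(tpm=tpm, genes=genes)


def _pheno(acc_ids, **traits):
    rows = []
    for trait, vals in traits.items():
        for a, v in zip(acc_ids, vals):
            rows.append({"accession_id": a, "trait": trait, "year": 2020, "value": v})
    return PhenotypeTable(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ICA module recovery
# ---------------------------------------------------------------------------

def _planted_expression(seed=0, n_genes=100, n_acc=80):
    rng = np.random.default_rng(seed)
    f1 = rng.laplace(size=n_acc)  # non-Gaussian sources for ICA
    f2 = rng.laplace(size=n_acc)
    X = 0.3 * rng.standard_normal((n_genes, n_acc))
    mod1 = list(range(0, 15))
    mod2 = list(range(40, 55))
    for i in mod1:
        X[i] += (1.0 + 0.2 * rng.standard_normal()) * f1
    for i in mod2:
        X[i] += (1.0 + 0.2 * rng.standard_normal()) * f2
    gene_ids = [f"g{i}" for i in range(n_genes)]
    acc_ids = [f"a{i}" for i in range(n_acc)]
    ex = _expr_matrix(X, gene_ids, acc_ids)  # has negatives: no log transform
    return ex, {f"g{i}" for i in mod1}, {f"g{i}" for i in mod2}, f1, f2


def test_run_ica_recovers_planted_modules():
    ex, mod1, mod2, f1, f2 = _planted_expression()
    modules = run_ica(ex, n_components=2, n_runs=8, seed=0)
    assert len(modules) == 2
    for planted, factor in ((mod1, f1), (mod2, f2)):
        best = max(
            modules,
            key=lambda m: len(planted & set(m.member_genes)) / len(planted | set(m.member_genes)),
        )
        jac = len(planted & set(best.member_genes)) / len(planted | set(best.member_genes))
        assert jac >= 0.7
        r = abs(np.corrcoef(best.eigen_expression.to_numpy(), factor)[0, 1])
        assert r > 0.9  # eigengene tracks the planted factor
        assert best.stability > 0.8


def test_run_ica_input_validation():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 15))
    X[3] = 0.0  # constant gene
    ex = _expr_matrix(X, [f"g{i}" for i in range(20)], [f"a{i}" for i in range(15)])
    with pytest.raises(ValueError, match="constant gene"):
        run_ica(ex, n_components=3)
    X[3] = rng.standard_normal(15)
    ex = _expr_matrix(X, [f"g{i}" for i in range(20)], [f"a{i}" for i in range(15)])
    with pytest.raises(ValueError, match="components"):
        run_ica(ex, n_components=15)


# ---------------------------------------------------------------------------
# eigengene-trait association
# ---------------------------------------------------------------------------

def _mk_module(comp, eigen, acc_ids, genes=("gX",)):
    return ICAModule(
        component=comp,
        gene_weights=pd.Series(np.ones(len(genes)), index=list(genes)),
        member_genes=list(genes),
        eigen_expression=pd.Series(eigen, index=acc_ids),
    )


def test_module_trait_correlation_matches_pearson_and_bh():
    rng = np.random.default_rng(2)
    n = 60
    acc = [f"a{i}" for i in range(n)]
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    t1 = e1 + 0.3 * rng.standard_normal(n)  # tied to module 0
    t2 = rng.standard_normal(n)             # noise
    mods = [_mk_module(0, e1, acc), _mk_module(1, e2, acc)]
    pheno = _pheno(acc, alpha=t1, beta=t2)
    assocs = module_trait_correlation(mods, pheno)
    assert len(assocs) == 4
    # oracle: direct pearson and a recomputed BH correction
    ps = []
    for a in assocs:
        e = {0: e1, 1: e2}[a.module]
        y = {"alpha": t1, "beta": t2}[a.trait]
        r, p = stats.pearsonr(e, y)
        assert a.r == pytest.approx(float(r))
        assert a.p == pytest.approx(float(p))
        ps.append(p)
    q = stats.false_discovery_control(ps, method="bh")
    for a, qv in zip(assocs, q):
        assert a.q == pytest.approx(float(qv))
    strong = [a for a in assocs if a.module == 0 and a.trait == "alpha"]
    assert strong[0].q < 0.01 and abs(strong[0].r) > 0.8

    few = [_mk_module(0, e1[:5], acc[:5])]
    with pytest.raises(ValueError, match="shared accessions"):
        module_trait_correlation(few, _pheno(acc[:5], alpha=t1[:5]))


def test_module_gwas_maps_eigengene_to_driving_variant():
    rng = np.random.default_rng(3)
    n, m = 200, 25
    D = rng.integers(0, 3, size=(n, m)).astype(float)
    g = make_geno(D)
    acc = g.accessions["id"].to_list()
    eigen = D[:, 7] + 0.3 * rng.standard_normal(n)
    mod = _mk_module(0, eigen, acc)
    grms = {"*": GRM(matrix=np.eye(n), variant_idx=np.arange(m))}
    loci, res = module_gwas(mod, g, grms, threshold_p=1e-6)
    assert len(loci) >= 1
    assert loci[0].lead == "v7"
    assert res.loc[7, "p"] < 1e-20
    with pytest.raises(ValueError, match="constant eigen"):
        module_gwas(_mk_module(0, np.zeros(n), acc), g, grms, threshold_p=1e-6)


# ---------------------------------------------------------------------------
# module-level distal regulation vs shared-seed oracle
# ---------------------------------------------------------------------------

def test_module_distal_test_matches_replayed_null():
    genome_genes = [f"g{i}" for i in range(200)]
    # locus A distally regulates g0..g19; locus B regulates g50..g54
    recs = [
        EQTLRecord(gene=f"g{i}", lead=f"v{i}", lead_idx=i, chrom="chr3",
                   pos=2_000_000 + 1000 * i, p=1e-9, n_proxies=2, klass="distal")
        for i in range(20)
    ] + [
        EQTLRecord(gene=f"g{i}", lead=f"v{i}", lead_idx=i, chrom="chr4",
                   pos=7_000_000 + 1000 * i, p=1e-9, n_proxies=2, klass="distal")
        for i in range(50, 55)
    ]
    loci = [("chr3", 2_000_000, 2_100_000), ("chr4", 7_000_000, 7_100_000)]
    module = [f"g{i}" for i in range(15)] + ["g100", "g101"]  # 15 hits at locus A
    n_perm, seed, alpha = 300, 5, 0.01
    table, threshold = module_distal_test(
        module, loci, recs, genome_genes, n_perm=n_perm, alpha=alpha, seed=seed
    )
    assert table["observed"].tolist() == [15, 0]

    # replay the permutation null with the identical seed and draw order
    rng = np.random.default_rng(seed)
    gg = np.array(genome_genes)
    locus_sets = [
        {r.gene for r in recs if r.chrom == c and s <= r.pos <= e}
        for c, s, e in loci
    ]
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        draw = set(gg[rng.choice(len(gg), size=len(module), replace=False)])
        null_max[b] = max(len(ls & draw) for ls in locus_sets)
    assert threshold == pytest.approx(float(np.quantile(null_max, 1 - alpha)))
    assert bool(table.loc[0, "passes"]) is (15 > threshold)
    assert not table.loc[1, "passes"]
    assert table.loc[0, "passes"]  # 15/17 module genes at one locus must pass

    with pytest.raises(ValueError, match="module larger"):
        module_distal_test(genome_genes + ["extra"], loci, recs, genome_genes)


# ---------------------------------------------------------------------------
# submodules and per-gene correlations
# ---------------------------------------------------------------------------

def test_partition_submodules_separates_planted_blocks():
    rng = np.random.default_rng(6)
    n_acc = 60
    base1 = rng.standard_normal(n_acc)
    base2 = rng.standard_normal(n_acc)
    rows, ids = [], []
    for i in range(8):
        rows.append(np.exp(base1 + 0.3 * rng.standard_normal(n_acc)))
        ids.append(f"b1_{i}")
    for i in range(8):
        rows.append(np.exp(base2 + 0.3 * rng.standard_normal(n_acc)))
        ids.append(f"b2_{i}")
    ex = _expr_matrix(np.array(rows), ids, [f"a{i}" for i in range(n_acc)])
    labels = partition_submodules(ids, ex, corr_min=0.3, min_size=3, seed=0)
    lab1 = {labels[f"b1_{i}"] for i in range(8)}
    lab2 = {labels[f"b2_{i}"] for i in range(8)}
    assert len(lab1) == 1 and len(lab2) == 1 and lab1 != lab2
    with pytest.raises(ValueError, match="at least 3"):
        partition_submodules(ids[:2], ex)


def test_gene_trait_correlations_dual_flag_and_oracle():
    rng = np.random.default_rng(7)
    n = 80
    acc = [f"a{i}" for i in range(n)]
    shared = rng.standard_normal(n)
    t1 = shared + 0.3 * rng.standard_normal(n)
    t2 = shared + 0.3 * rng.standard_normal(n)
    g_dual = np.exp(shared)              # correlated with both traits
    g_none = np.exp(rng.standard_normal(n))
    g_const = np.full(n, 3.0)
    ex = _expr_matrix(np.array([g_dual, g_none, g_const]),
                      ["gDual", "gNone", "gConst"], acc)
    pheno = _pheno(acc, sw=t1, oil=t2)
    tab = gene_trait_correlations(["gDual", "gNone", "gConst"], ex, pheno)
    row = tab.set_index("gene")
    assert bool(row.loc["gDual", "dual"]) and bool(row.loc["gDual", "concordant"])
    assert not row.loc["gNone", "dual"]
    assert bool(row.loc["gConst", "excluded_constant"])
    # oracle for one cell
    r, p = stats.pearsonr(np.log1p(g_dual), t1)
    assert row.loc["gDual", "r_sw"] == pytest.approx(float(r))
    assert row.loc["gDual", "p_sw"] == pytest.approx(float(p))
    with pytest.raises(ValueError, match="shared accessions"):
        gene_trait_correlations(["gDual"], ex, _pheno(acc[:5], sw=t1[:5], oil=t2[:5]))


# ---------------------------------------------------------------------------
# promoter motif enrichment
# ---------------------------------------------------------------------------

def test_motif_enrichment_flags_planted_motif():
    from Bio import motifs
    from Bio.Seq import Seq

    motif = motifs.create([Seq("TGACGTCA")] * 6)
    motif.name = "bZIP_like"
    rng = np.random.default_rng(8)

    def rand_seq(k):
        return "".join(rng.choice(list("ACGT"), size=k))

    member = {f"m{i}": rand_seq(40) + "TGACGTCA" + rand_seq(40) for i in range(15)}
    background = {f"b{i}": rand_seq(90).replace("TGACGTCA", "TTTTTTTT")
                  for i in range(200)}
    out = motif_enrichment(member, background, [motif], hit_threshold=7.0)
    assert len(out) == 1
    e = out[0]
    assert e.hits_in_module == 15
    assert e.p < 1e-6
    assert e.fold > 3 or e.hits_in_background == 0
    assert np.isfinite(e.q)
    # FPR-derived threshold branch finds the planted site too
    auto = motif_enrichment(dict(list(member.items())[:3]),
                            dict(list(background.items())[:10]), [motif])
    assert auto[0].hits_in_module == 3
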