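# seedomics

An integrative genomics toolkit for dissecting seed-weight and oil-content
variation in a resequenced soybean population: mixed-model GWAS, expression
QTL mapping, ICA coexpression modules, transcriptome-wide association, and
domestication selection scans — together with a fully parameterised
synthetic-data generator that stands in for the real study and carries a
machine-readable truth table for every planted signal.

## What it does

| Module | Contents |
| --- | --- |
| `seedomics.simdata` | Synthetic study generator: structured genotypes (Gaussian-copula AR(1) LD, subpopulations and families), expression with planted local eQTLs / trans hotspots / coexpression modules, bivariate traits with a planted genetic correlation, domestication panels with a planted sweep. |
| `seedomics.genotypes` | VCF reading with genotype-level GQ/DP filters, MAF/missingness, LD (r², D′ with CIs, blocks), GRM and leave-one-chromosome-out GRMs, LD pruning, PCA. |
| `seedomics.mlm_assoc` | Single-component REML mixed model with LOCO kinship, eigenvalue-based effective-number-of-tests thresholding, greedy LD clumping, bivariate GREML genetic correlation, cross-trait signed-t correlation. |
| `seedomics.eqtl` | Expression filtering, rank-based inverse-normal transform, genome-wide eQTL mapping with proxy support and block merging, local/distal classification (1 Mb), permutation-calibrated trans-hotspot detection, open-chromatin enrichment. |
| `seedomics.coexpr` | Multi-run matched FastICA modules with stability indices, eigengene–trait correlation (BH), eigengene GWAS, module-level distal-regulation permutation test, Louvain submodules, per-gene dual-trait correlations, promoter motif enrichment. |
| `seedomics.twas` | Cis-heritability screening (REML LRT), expression weights (top1/BLUP/lasso/elastic net, CV-selected), summary-statistic TWAS Z through a shrunken LD reference, candidate calling at \|Z\| ≥ 3, packaged published candidate table. |
| `seedomics.popgen` | Windowed nucleotide diversity, π-ratio sweep scans against genome-wide quantile thresholds, windowed Weir–Cockerham FST, haplotype spectra. |
| `seedomics.alleles` | Superior-allele definition from effect signs, aggregation with a top/bottom rank-sum test, MAF-versus-effect architecture profiles. |
| `seedomics.cli` | `seedomics run` pipeline orchestration with stage seeding, dependency checking and a hash-carrying manifest; `seedomics simdata`; `seedomics filter-vcf`. |

See `docs/methods.md` for the statistical methods.

## Quick start

```bash
# end-to-end pipeline on a synthetic study
seedomics run --out run1 --seed 7

# write a synthetic fixture set (VCF, expression, phenotypes, truth tables)
seedomics simdata --out fixtures --seed 0
```

```python
from seedomics.simdata import SimConfig, simulate_study
from seedomics import genotypes, mlm_assoc

study = simulate_study(SimConfig(seed=1))
g = study.genotypes
grms = genotypes.loco_grms(g)
y = study.phenotypes.blue.loc[g.accessions["id"], "seed_weight"].to_numpy()
gwas = mlm_assoc.fit_mlm_loco(g, y, grms)
```

## Tests and acceptance

```bash
python -m pytest -q tests/                                  # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion:
bookkeeping identities, the packaged TWAS table, closed-form/brute-force
oracle equivalences, parameter recovery on planted synthetic studies, and
null calibration. `scripts/acceptance.py` runs the main computations on an
acceptance-scale study and writes the headline quantities as JSON.
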