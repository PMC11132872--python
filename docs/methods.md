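# Methods

Statistical methods implemented in `seedomics`, in pipeline order.

## Synthetic study generator (`simdata`)

Genotypes. Haplotypes are drawn from a Gaussian-copula model: per
chromosome, a latent AR(1) Gaussian field with correlation
`exp(-d / ld_decay_bp)` between sites distance `d` apart is thresholded at
`Phi^-1(p)` per site, so marginal allele frequencies are exact while LD
decays exponentially with distance. Allele frequencies are hierarchical:
a locally smooth ancestral frequency in `(maf_floor, 1 - maf_floor)` is
perturbed per subpopulation by a Balding–Nichols draw calibrated to
`target_fst`, then per family (nested in subpopulation, `family_size`
accessions) by a second draw at `family_fst`. Dosages are the sum of two
haplotypes; a configurable fraction of cells receives filter-tripping
GQ/DP values when written to VCF.

Expression. A fraction of genes receives a planted local eQTL at a nearby
"taggable" variant (at least two LD proxies at r² ≥ 0.6 within 250 kb, so
the signal is discoverable by proxy-supported mapping). Trans hotspots are
common variants that drive `genes_per_hotspot` distal genes; hotspot 0
acts through a module's latent factor (coupling a coexpression module to a
genetic regulator), the others through independent per-target effects.
Modules are gene sets sharing a latent per-accession profile; shared
background factors give the expression matrix a realistic low-rank
structure. All planted links are recorded in a truth table.

Traits. Two traits with heritabilities `trait_h2` and genetic correlation
`trait_rg`. Polygenic effects on the standardised-dosage scale are drawn
from a bivariate normal with correlation `trait_rg`; a small block of
mediator genes contributes expression-mediated effects whose pleiotropic
term is solved analytically (Brent root-finding) so the expected genetic
correlation equals `trait_rg` exactly rather than in expectation over
random effect signs. A non-genetic module profile correlates one module
with both traits at `module_trait_r`.

Panels. Three domestication panels (wild, landrace, cultivar) share one
variant set; a designated region on chromosome 1 has one haplotype swept
to increasing frequencies across panels, depressing diversity.

## Mixed-model association (`mlm_assoc`)

The single-random-effect model `y = mu + x b + g + e`, `g ~ N(0, sg² K)`,
is fitted by eigendecomposition of the kinship: the REML likelihood is
profiled over h² on the null model (bounded scalar maximisation), then
every variant receives a generalised-least-squares effect, SE and normal
p-value under those variance components. Kinship is the GCTA-style GRM
`(x - 2p)(x - 2p)' / 2p(1-p)`, averaged over variants, with
leave-one-chromosome-out (LOCO) versions for association so the tested
variant never contributes to its own correction.

Multiple testing uses an eigenvalue-based effective number of tests
(simpleM): per 200-variant window, the number of leading eigenvalues of
the dosage correlation matrix covering 99.5% of its trace, summed
genome-wide; the threshold is 0.05 / M_eff. Significant results are
grouped by greedy PLINK-style clumping (p1/p2/r²/kb semantics).

Bivariate GREML estimates 2×2 genetic and residual covariance matrices by
rotating both traits into the GRM eigenbasis, where the likelihood
factorises over n independent 2×2 blocks. Vg and Ve are
Cholesky-parameterised (positive semidefinite by construction) and
maximised by multi-start Nelder–Mead; SE(rg) comes from the numerical
Hessian by the delta method. The genetic correlation is
`rg = Vg12 / sqrt(Vg11 Vg22)`.

## eQTL mapping (`eqtl`)

Expression is filtered (TPM ≥ 5 in > 5% of accessions, 95th/5th percentile
fold ≥ 2) and each gene rank-based inverse-normal transformed. Every gene
is tested against every variant with the LOCO mixed model (rotated
genotypes shared across genes). Suggestive associations (p < 1e-4) are
clumped (r² 0.2, 250 kb); a lead is retained when it beats the study-wide
1/m threshold and carries ≥ 2 LD proxies; same-gene leads in one haplotype
block merge into the most significant one. Leads within 1 Mb of the gene
span are local, others distal.

Trans hotspots: distinct distal-eGene counts in 1 Mb windows stepped by
100 kb are compared against a permutation null that relocates distal leads
uniformly within their chromosome (gene links and per-chromosome counts
preserved) and records the genome-wide maximum window count; windows
strictly above the 99th percentile of that maximum pass, and overlapping
passing windows merge. Open-chromatin enrichment relocates OCR intervals
(lengths preserved) and reports the empirical p `(1 + #null ≥ obs)/(B+1)`.

## Coexpression modules (`coexpr`)

FastICA is run repeatedly from seeded starts on the standardised
expression matrix (rank chosen by a PCA variance cutoff); components are
matched across runs by optimal assignment on absolute gene-weight
correlation, sign-aligned and averaged, with the mean matched |r| as a
stability index. Module membership is |weight| > 2 SD. Eigengenes
(per-accession component scores) are correlated with trait BLUEs
(Benjamini–Hochberg across modules × traits) and mapped by MLM-LOCO GWAS.
A module-level permutation test asks whether candidate loci distally
regulate more module genes than size-matched random gene sets (null
maximum across loci, 99th percentile, strict exceedance). Submodules come
from Louvain partition of the |Spearman| ≥ 0.3 gene graph; per-gene
dual-trait correlations flag genes significant for both traits. Promoter
motif enrichment scans PWM log-odds on both strands and tests hit counts
hypergeometrically.

## TWAS (`twas`)

Genes pass a cis-heritability screen: single-component REML on a kinship
from ±500 kb cis variants, likelihood-ratio against h² = 0 on the boundary
mixture `0.5 chi²(0) + 0.5 chi²(1)`. Expression weights are fitted by
top1, ridge/BLUP, lasso and elastic net; the model with the best
out-of-fold predictive R² is kept (genes predicted no better than the mean
are dropped). The association statistic combines GWAS z-scores through
the reference LD matrix, `Z = w'z / sqrt(w' R w)` with
`R <- 0.9 R + 0.1 I`, so a single-indicator weight reproduces that
variant's GWAS z exactly. Candidates satisfy |Z| ≥ 3 (optionally jointly
with an eGWAS |Z| ≥ 3). A published soybean seed-weight/oil-content
candidate table ships with the package.

## Selection scans (`popgen`)

Windowed π sums per-site unbiased heterozygosity `2p(1-p) n/(n-1)` (n =
non-missing allele count) over 100 kb windows stepped by 10 kb, divided by
the window length. The sweep scan takes the ratio of two panels' π per
window and flags windows at or above the genome-wide `(1 - top_frac)`
quantile; x/0 windows are capped at the largest finite ratio, 0/0 windows
are excluded. Windowed FST sums per-site Weir–Cockerham variance
components a, b, c and reports `sum(a) / sum(a+b+c)`. Haplotype spectra
count phased haplotypes over defining variants (unphased panels fall back
to unambiguous homozygous diplotypes).

## Superior alleles (`alleles`)

For each candidate gene the superior allele at its lead GWAS variant is
the allele whose dosage increases the trait. Per-accession superior-allele
dosages are summed over candidates and compared between the top-k and
bottom-k accessions by trait BLUE with a two-sided Wilcoxon rank-sum test.
The MAF–effect profile re-signs significant effects to the minor allele
and summarises the architecture by the Spearman correlation of MAF with
|effect| and the sign balance per MAF bin.

## Pipeline (`cli`)

`seedomics run` executes the enabled stages in dependency order on one
shared synthetic study. Per-stage seeds fan out deterministically from the
global seed (`seed · 1000003 + crc32(stage) mod 2³¹-1`). A JSON manifest
records parameters, seeds, outputs and SHA-256 hashes; reruns with an
unchanged configuration skip stages whose outputs already exist, and any
stage failure halts the run with a stage-scoped error and a partial
manifest on disk.
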