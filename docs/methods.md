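# Methods

## Presence/absence genotyping from coverage

A gene's genotype in an accession is decided by **breadth of coverage**
over the union of its CDS intervals: the fraction of CDS bases covered at
depth ≥ `min_depth` (default 1). The gene is called *present* when breadth
≥ 0.95, inclusive, and *absent* otherwise. Breadth is carried as an exact
ratio of two integers (covered bases / union length) and the threshold is
converted to an exact rational before comparison, so a gene with exactly
95% of its CDS covered is present regardless of floating-point
representation.

Two readings of "CDS coverage" are possible — breadth, or depth normalized
by mapped reads. Only breadth is dimensionless, so only breadth supports a
0.95 cutoff; the normalized mean depth (depth per million mapped reads,
scale constant 10⁶) is computed alongside as a QC covariate and never
enters the call. For genes with multiple (possibly overlapping, multi-
isoform) CDS records, coverage is cumulative over the **union** of the
intervals: each genomic base counts once.

Coordinates: GFF3 annotation is 1-based inclusive, depth tracks are
0-based half-open (mosdepth per-base dialect); all internal arithmetic is
half-open. Coverage is computed by interval intersection against the
run-length-encoded track (cumulative sums + binary search); chromosomes
are never materialized per-base. Strand is parsed but ignored — coverage
is strand-agnostic.

**Missing calls.** A cell is *missing* (not absent) when its accession
fails sample QC: zero mapped reads, or genome-wide mean depth below a
configurable floor (default 1×). Missingness is a sample property, not a
gene property; the downstream <15% missing marker filter is reachable
through these rules or through the generator's optional cell masking.

## Pan-genome classification

With occupancy *o* out of *n* classifiable accessions and *f* = *o*/*n*:
core *f* = 1; softcore 0.97 < *f* < 1; shell 0.01 ≤ *f* ≤ 0.97; cloud
0 < *f* < 0.01; a gene observed nowhere is labelled `absent_everywhere`
and excluded from the four-way partition. Core takes precedence over the
softcore band (whose verbal definition ">97%" would otherwise include
*f* = 1), and the shell bounds are inclusive: in a 268-accession cohort
the smallest softcore occupancy is 260 (97.01%), 259 (96.64%) and 3
(1.12%) are shell, and 2 (0.75%) is cloud. Missing calls count as absent
by default (`as_absent`); `drop_from_denominator` instead classifies over
non-missing calls only.

**Saturation curves** are prefix-of-permutation rarefaction: for a random
ordering of accessions and each prefix size *n*, core(*n*) counts genes
present in all *n* accessions and pan(*n*) genes present in at least one.
Defaults: 100 permutations, percentile CI 2.5/97.5. For ≤ 8 samples an
exhaustive mode enumerates every ordering, making the means exact subset
expectations (used by the tests against the closed-form
∑ᵢ C(oᵢ, n)/C(N, n) oracle). Core is non-increasing and pan
non-decreasing along every individual ordering, not only in the mean.

## Population structure

Markers are haploid binary alleles (present/absent). Pairwise distance is
the **p-distance**: the proportion of differing calls among genes
non-missing in both accessions. The tree is **Saitou–Nei neighbour
joining** on that matrix (via scikit-bio); negative branch lengths are
clamped to zero and flagged. PCA encodes calls 0/1, mean-imputes missing
cells per gene, centres by presence frequency and by default divides by
√(p(1−p)) (GRM-style standardization), then eigendecomposes the
sample-by-sample covariance; coordinates are eigenvectors scaled by root
eigenvalues, with each component's sign fixed so its largest-magnitude
entry is positive.

## F_ST on binary gene content

Treating each accession's call as one haploid allele avoids inventing
heterozygotes that the data cannot contain. Two estimators are provided:

- **Weir–Cockerham (default)**: the variance-component estimator
  specialized to haploid counts, θ̂ = (MSP − MSG)/(MSP + (n_c − 1)MSG),
  with MSP/MSG the between/within mean squares of the 0/1 allele values
  and n_c = n − ∑nᵢ²/n for two populations.
- **Hudson**: 1 − H_w/H_b with unbiased within-population heterozygosity
  p̂(1−p̂)·n/(n−1) and H_b = p̂₁(1−p̂₂) + p̂₂(1−p̂₁).

Per-gene estimates are reported **raw** — negative values are never
clamped, so the top-1% scan is independent of any clamping policy. A gene
is flagged undefined when monomorphic across both populations or when
either population has fewer than two non-missing calls. The scan threshold
is the empirical (1 − fraction) quantile of defined estimates with linear
interpolation (numpy's default, stated because "top 1%" is ambiguous at
small counts); ties at the threshold are all flagged.

For **genome-wide** differentiation the per-locus components are summed
before the ratio is taken (`fst_global`), with a leave-one-locus-out
jackknife SE. The mean of per-locus ratios is *not* used as a summary:
with two populations MSP carries a single degree of freedom, so per-locus
ratios scatter enormously and their mean is Jensen-biased downward by
30%+ at strong differentiation, whereas the ratio-of-sums recovers the
generating Balding–Nichols F within MC error (verified for
F ∈ {0.05, 0.2, 0.4} in the acceptance suite).

## Association models

Phenotype is the binary wild(0)/selection(1) label treated as continuous —
the convention of Gaussian mixed-model GWAS tools on case/control-like
traits. Markers are mean-imputed 0/1 presence calls.

- **Marker QC**: keep a gene iff MAF > 0.05 *and* missing rate < 0.15,
  both strict — a marker exactly at either bound is removed. MAF is the
  minor presence-state frequency over non-missing calls.
- **Kinship**: VanRaden-type, K = ZᵀZ / ∑pⱼ(1−pⱼ) with Z the
  frequency-centred calls; eigenvalues floored at 0 so K is PSD.
- **GLM**: per-marker OLS with intercept and optional PC covariates;
  Wald t-test on the marker coefficient. Implemented by residualizing on
  the covariates once (Frisch–Waugh), which is algebraically identical to
  the full per-marker OLS (cross-checked against statsmodels to 1e-10).
  Perfect-fit markers report p = 0; markers collinear with the covariates
  are flagged NaN.
- **MLM**: EMMA-style. K is eigendecomposed once; the variance ratio
  δ = σ²_e/σ²_g is estimated by REML on the null model (coarse grid over
  log δ ∈ [−10, 10] then Brent refinement; the grid is the fallback if
  refinement fails) and held fixed across markers (P3D) for determinism
  and speed. Each marker is then tested by GLS in the eigenbasis, which
  reduces to weighted OLS. With K = I the procedure collapses exactly to
  the GLM (verified to 1e-8).
- **Fisher baseline**: two-sided Fisher exact test on the 2×2
  presence-by-phenotype table; effect is the log odds ratio with
  Haldane–Anscombe correction when a cell is empty.
- **Significance**: both a Bonferroni flag (p ≤ α/m, α = 0.05) and a fixed
  line (−log10 p ≥ 5) are always reported, so either convention can be
  read off. Q–Q expected quantiles are −log10((i − 0.5)/m);
  λ_gc = median(χ²_obs)/χ²₀.₅(1). The number of PC covariates defaults
  to 3 and is configurable.

## The synthetic cohort generator

The generator emulates the study conditions the analyses are sized for:
268 accessions (91 wild + 177 selection), 1000 genes, 77.23% core. Its
defaults are the cohort every driver and acceptance test uses.

- **Occupancy spectrum**: variable genes draw an ancestral presence
  frequency p ~ Beta(0.8, 0.8) — a mildly U-shaped spectrum typical of
  accessory genomes. The real occupancy spectrum of any particular
  species is not parametrically known; this shape is a modelling knob,
  not a claim.
- **Differentiation**: Balding–Nichols — population frequencies
  p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) independently per population, so the
  expected F_ST equals the target F. The default F = 0.1 was calibrated
  so the cohort's empirical top-1% per-gene F_ST threshold lands near
  0.40, the value such wild-vs-domesticated scans report at this cohort
  size.
- **Selection-shifted genes**: presence frequencies pinned explicitly;
  the default triple is (0.5952 → 0.2621) — a transposon-derived gene
  strongly depleted by selection — plus two genes ~10% absent in the wild
  and fixed under selection.
- **Depth emission** is interval-wise, not read-level: present genes get
  chunked (≤50 bp) positive-Poisson depth at mean 20× with a random
  leading cut of ≤2% of the CDS union (realized breadth ≥ 0.98 by
  construction); absent genes get a leading stretch of depth 1–2 covering
  at most `background_breadth` (default 0.3) of the CDS — background
  mismapping. Mapped-read totals are proportional to summed depth
  assuming ~100 bp reads. Gene models have 1–3 CDS exons of 60–140 bp on
  10 chromosomes, with 2% of genes on unplaced `novel_*` contigs.
- Everything is reproducible byte-for-byte from the config seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level artefacts (mapping-quality
loss, GC bias, duplicated regions), partial gene deletion (truth is
all-or-nothing per gene), linkage between genes (PAVs are independent, as
the per-gene analyses assume), and within-population substructure beyond
the two labels. Real cohorts also entangle relatedness with the
phenotype: on the default cohort, where the phenotype *is* the population
label, structure-corrected association models are calibrated but
conservative (driver 06), and the F_ST scan is the appropriate instrument
for population-differentiated gene content; the MLM's power is
demonstrated separately under familial (phenotype-orthogonal) structure.

## Problem sizes

Tests and drivers run at: 268 × 1000 for end-to-end recovery; 2000 loci
for F_ST parameter recovery; 2000 markers × 10 replicates for MLM
calibration; 200 replicates for NJ recovery and MLM power; 1000 random
configurations for the exact coverage and F_ST oracles. These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
full suite under a minute of compute.

## Known limitations

- The MLM is Gaussian on a 0/1 phenotype; a logistic mixed model is out
  of scope, matching common GWAS-tool practice.
- Multi-locus models (FarmCPU-style) and ML tree inference are not
  implemented; the model comparison is GLM vs MLM vs Fisher.
- The NJ implementation delegates to scikit-bio; tie-breaking among equal
  Q-matrix entries follows its internal deterministic order.
- VCF round-trips preserve calls and gene locations exactly, but
  annotation CDS structure only survives through the GFF, not the VCF.
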