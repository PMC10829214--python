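# Methods

`adipoage` reimplements, at desk scale, an analysis pipeline linking adipose
stem/precursor-cell (ASPC) biology to age-obesity interactions: single-cell
marker and age-DE calling, reference-based deconvolution of bulk expression
with stratified proportion comparisons, genotype QC and GWAS, regional
polygenic risk scores (PRSs) fitted from summary statistics, PRS-by-age and
variant-by-age interaction testing, and a random-gene-set permutation null.
All inputs come from the package's own synthetic-cohort generator, so every
stage runs offline and every planted truth is recoverable.

## The synthetic cohort

**Genotypes.** Dosages are sums of two independent haplotypes drawn from a
Gaussian copula: latent standard normals follow an AR(1) process with
correlation `ld_rho` inside fixed-length LD blocks (default 200 kb) and are
independent across blocks and chromosomes; a haplotype carries the alternate
allele where its latent value falls below `Phi^{-1}(MAF)`, with MAFs uniform
on (0.05, 0.5]. The realised allele correlation between neighbours is the
tetrachoric value implied by the thresholds, which the test suite checks by
numerical integration of bivariate-normal orthant probabilities. This model
is deliberately simple — no coalescent realism, recombination maps, or
population structure beyond additive PC covariates — but reproduces the two
properties the downstream methods rely on: blockwise LD for
clumping/penalized fitting, and exchangeable unrelated individuals for OLS.

**Phenotype.** BMI (kg/m²) is generated as

    bmi = 27 + G + 0.05·age_c + γ·age_c·S + 1.0·I(male) + covariate terms + ε

where `G` is an additive polygenic term over 80 causal variants sampled
genome-wide, scaled so its variance equals `h² · 25 = 6.25` (h² = 0.25 on a
25 kg²/m⁴ variance scale), ages are uniform on 25–73 years (spanning the
adult biobank range), and `ε` is Gaussian with SD 4. `S` is the
**interaction score**: the main-effect-weighted genetic score of the causal
variants falling inside the ±500 kb cis-windows of the designated target
gene set, standardized to unit variance. Weighting the burden by the main
effects (rather than counting alleles) encodes the generative assumption the
regional-PRS analysis relies on — that the cis variants carrying main
effects on BMI are the ones whose effects age modulates — and makes γ
interpretable in kg/m² per year per SD of regional genetic score.

The default γ = −0.08 was calibrated, at the default study scale, so that a
single replicate of the full pipeline yields an interaction Wald p of order
10⁻² (p ≤ 0.01 in about 80% of replicates; the distribution of p across
replicates is heavy-tailed because split-validation occasionally selects a
weakly regional candidate, so the median sits well below 0.01).

**Single-cell data.** Five cell types (adipocyte, ASPC, myeloid, vascular,
T cell) with base proportions (0.45, 0.20, 0.15, 0.12, 0.08). Per donor,
cell-type counts are multinomial; per cell, gene counts are Poisson around
the type's mean-expression profile. The ASPC fraction declines linearly with
age (0.002/year around the age midpoint of 49) **only** in donors below the
BMI gate of 30; donors at or above the gate sit at a constant 0.05 deficit
with no age term — the "obesity abolishes the age decline" structure the
stratified comparisons are designed to detect. Age-DE effects are
multiplicative on ASPC-cell means: a gene with planted log2 fold change `f`
is scaled by `2^(f·z)` with `z = (age − 49)/24`, so the young and old donor
halves differ by about `2^f`-fold. Default fixture: 40 donors (half with BMI
20–24.5, half 30–38), 300 cells each, 120 genes with 12 planted markers per
type at 8-fold elevation.

Features of real single-nucleus data the generator does **not** emulate:
dropout beyond Poisson sparsity, ambient RNA, doublets, donor-level
expression variability, and batch structure. Passing tests therefore show
the statistical machinery is correct under clean compositional and Poisson
noise, not that it is robust to those artefacts. One consequence worth
knowing: because expression is normalized per cell, planting strong age
effects on high-expressed marker genes shifts the normalized values of *all*
genes in ASPC cells (a compositional effect), so the age-DE test can
legitimately flag un-planted genes at large cell counts.

**Bulk mixtures.** Expected expression is `Z·p` scaled to the library size,
with mean-one log-normal multiplicative noise of a chosen coefficient of
variation. Proportions live on the simplex by construction.

## Single-cell markers and age-DE

Counts are scaled to 1,000 per cell and log1p-transformed. Marker calling is
one-vs-rest two-sided Wilcoxon rank-sum per cell type, keeping upregulated
genes with log2 fold change ≥ 0.25 (computed on the linear normalized scale)
expressed in ≥ 10% of in-type cells, Bonferroni-adjusted p < 0.05. The
Bonferroni denominator is the number of genes in the dataset per comparison
(the discovery-tool convention; it also absorbs the selection bias of the
fold-change prefilter — adjusting only over prefiltered genes inflates the
family-wise error, which the null-fixture test demonstrates). A
replication-style variant with log2FC ≥ 0.1 is available through the
parameters. Unique ASPC markers are the focal-type markers minus any gene
marking another type, ordered by ascending p.

Age-DE uses cells (not donors) as the Wilcoxon sampling unit, grouping cells
by donor age class: median split by default, or lowest-vs-highest age
quartile (young = at or below the 25th percentile, old = strictly above the
75th). The Wilcoxon wrapper uses the exact null distribution whenever both
groups are small and tie-free, otherwise the normal approximation with tie
and continuity corrections; a fully tied input returns p = 1.

## Deconvolution

The reference profile `Z[g, t]` is the mean CPM-normalised expression of
gene g over all cells of type t pooled across donors ("Bisque-style,
simplified": pseudobulk reference → optional overlap-sample linear transform
→ constrained least squares; the full variance-weighting of the original
tool is not reproduced). When overlap samples exist in both the single-cell
and bulk data, a per-gene least-squares line from pseudobulk to bulk is
inverted to put bulk on the reference scale (genes with non-positive slope
or < 3 overlap points fall back to moment matching). Each bulk sample is
decomposed by NNLS and renormalised to the simplex, which makes the
estimates exactly scale-invariant and exact on noise-free mixtures.
Stratified comparisons report the Mann-Whitney U of the first group (the
rank sum minus its minimum), matching the convention of common statistical
software, with optional seeded down-sampling to equalise group sizes.

## GWAS

QC drops variants with missingness ≥ 1%, folded MAF < 1%, or HWE chi-square
p < 10⁻⁶ (the conventional threshold; the filter itself is standard but the
source analyses do not state a value), and individuals with genotype
missingness > 1% or heterozygosity beyond ±3 SD of the cohort mean (a
stand-in for tool defaults; configurable). Association is OLS of the
within-stratum inverse-normal-transformed trait on dosage plus covariates
(top PCs, center, array, sex; optionally centered age and age²), computed by
the Frisch-Waugh projection so the scan vectorises; this is algebraically
the joint fit, which the suite asserts against a normal-equation oracle. OLS
replaces the mixed model of large-biobank practice because the synthetic
cohorts are unrelated and unstructured. Monomorphic variants are emitted
flagged with beta 0 and p 1. A post-filter removes MAF < 1% and INFO < 0.8.

## Regional PRS

Cis-windows are gene body ± 500 kb, 0-based half-open, merged when they
overlap, with sex-chromosome genes dropped for regional scores; a 1-based
position p is inside [s, e) iff s < p ≤ e. Candidate variants are restricted
to the windows **before** penalized fitting, matching a regional-score
design in which only local variants enter the model.

The penalized fit solves, per LD block, the lasso whose stationarity
condition is `w_j ← soft(r_j − Σ_{k≠j} B_jk w_k, λ) / B_jj` with
`B = (1−s)R + sI` (unit diagonal, so `B_jj = 1`), where
`r_j = β_j / sqrt(β_j² + (n−2)·se_j²)` is the sign-preserving marginal
correlation recovered from the summary statistics. Coordinate descent runs
with warm starts down the λ path until the maximal KKT violation falls below
10⁻⁹ (500-sweep cap; non-converged fits are flagged but retained), and the
suite checks identity-LD closed forms, KKT conditions, and agreement with an
off-the-shelf convex solver on a correlated block. Default grids are
s ∈ {0.2, 0.5, 0.9, 1.0} with 20 λ values log-spaced on [0.001, 0.1] (the
published defaults' shape) for standalone fitting; the permutation pipeline
uses a reduced grid (s = 0.5; λ ∈ {0.002, 0.005, 0.02, 0.05}) applied
identically to the observed and permuted gene sets. The LD reference is
built from the base-split genotypes with block boundaries at the simulator's
LD blocks — a documented substitution for an external reference panel.

Scores are allele-frequency-centered weighted dosage sums, which makes them
exactly invariant to flipping a variant's coded allele. Split-validation
assigns test individuals to sex-stratified halves A/B, picks per half the
grid point whose score best correlates with the trait, applies it to the
opposite half, z-standardises each applied half and concatenates. Variance
explained is the squared Pearson correlation between score and trait.

## Interaction testing

The phenotype is residualised on PCs, center, array and sex, then
inverse-normal transformed. The headline model is OLS of adjusted BMI on
centered age, standardized PRS, and their product, with Wald t tests on
n − 4 df (exact under OLS normality; the t-vs-normal choice is immaterial at
these n). Age centering and PRS standardisation are numerical conveniences:
the interaction coefficient and its p are invariant, which is asserted to
1e-10. BMI classes are normal < 25 ≤ overweight < 30 ≤ obese; frequency
matching equalises (sex, age-year) cell counts between the normal and obese
groups by seeded down-sampling, dropping one-sided cells from both groups.

The single-variant scan filters candidates through region membership,
nominal GWAS significance (p < 0.05), greedy LD clumping (r² ≥ 0.1 within
±250 kb, most significant variant kept as index), and open-chromatin
overlap, logging the count surviving each stage; every attrition count is
checked exactly against planted truth in the suite. Variants are coded as
copies of the allele positively associated with BMI in the non-age-adjusted
GWAS, and Bonferroni correction spans the variants actually tested.

## Permutation null

The observed regional-PRS interaction p is ranked against p-values from
regional PRSs built on randomly drawn autosomal gene sets of the same gene
count (not variant count; a variant-count-matched mode would be a natural
sensitivity extension but window sizes legitimately differ across gene
sets). Each permutation runs the identical pipeline: windows → penalized fit
→ split-validated score → interaction OLS; gene sets whose windows hold no
variants are recorded as failures, and more than 5% failures aborts. The
percentile is the fraction of null p-values strictly exceeding the observed
one; alongside the raw rank an add-one empirical p, (1 + #{null ≤ obs}) /
(1 + n), is reported so the estimate can never be exactly zero. Significance
is percentile > 0.95. The `RegionalInteractionPipeline` precomputes
everything gene-set-independent so thousands of permutations run in seconds;
its equality with the composed module calls is asserted in the suite.

Because the default genome is small (two 20-Mb autosomes), the ±500 kb
windows of a random six-gene set overlap the target windows far more often
than in a real genome, so under a planted effect the null shows an elevated
nominal-significance fraction; the γ = 0 calibration (the 95th-percentile
call firing at its nominal 5% rate) is the clean check of the machinery.

## Problem sizes and numerical choices

The default study is 2,400 individuals (half base for GWAS, half test split
into A/B), a 40-Mb + 6-Mb genome carrying 78 genes and ~1,840 variants
(0.04/kb), and a 6-gene target set — sizes chosen so a full replicate with
hundreds of permutations runs in a couple of seconds and repeated-replicate
calibration studies stay within minutes on one CPU; the null-calibration
study runs replicates at 1,200 individuals, which leaves the type-I rate
unchanged. The lasso kernel is JIT-compiled (numba) with a pure-numpy
fallback of identical semantics. Degenerate inputs are handled explicitly:
constant traits and constant scores raise rather than emitting NaNs,
monomorphic variants are flagged, all-zero bulk samples are named in the
error, and proportion clipping in the single-cell generator warns.

## Known limitations

- The generator's realism limits are listed above; in particular no
  relatedness is simulated, so twin-design aspects of proportion comparisons
  (one-per-pair sampling) are exercised only as generic down-sampling.
- Clinical metabolic-health phenotyping (MUO/MHO definitions) is out of
  scope; stratified analyses take group labels as inputs.
- The deconvolution implements the documented skeleton of the
  reference-based approach, not the original tool's full weighting scheme.
- Regional R² values are not comparable to biobank-scale reports: the
  synthetic genome's cis-windows cover a much larger genome fraction.
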