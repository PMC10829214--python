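# adipoage

Age and obesity both deplete adipose stem and precursor cells (ASPCs), the
cell type that generates new fat cells and so determines whether adipose
tissue can expand in a metabolically healthy way. A recurring observation in
human subcutaneous adipose tissue is that the ASPC fraction declines with
age in normal-weight individuals but is *already low* in young obese
individuals — obesity prematurely induces the aging phenotype — and that
the genetic effect of variants near age-perturbed ASPC genes on BMI is
itself modulated by age in obese individuals.

`adipoage` is a Python library for studying exactly this class of question
at desk scale, end to end and fully offline. It bundles:

- **`adipoage.synthetic`** — a cohort generator producing LD-blocked
  genotypes (Gaussian-copula haplotypes), a BMI phenotype with a planted
  genotype-by-age interaction confined to the cis-windows of a target gene
  set, cell-type-annotated single-cell counts whose ASPC fraction declines
  with age only below a BMI gate, bulk mixtures, and open-chromatin
  intervals;
- **`adipoage.markers`** — one-vs-rest Wilcoxon marker calling, unique-ASPC
  marker filtering, and age differential expression across ASPC cells;
- **`adipoage.deconvolve`** — reference-based bulk deconvolution
  (pseudobulk profile → optional overlap-sample transform → NNLS) and
  stratified Wilcoxon proportion comparisons;
- **`adipoage.gwas`** — genotype/individual QC, rank-based inverse-normal
  transforms, and a vectorised OLS association scan;
- **`adipoage.prs`** — cis-window construction (gene body ± 500 kb), greedy
  LD clumping, penalized summary-statistic regression by blockwise
  coordinate descent on the shrunken LD matrix `(1−s)R + sI`,
  split-validated scoring, and variance explained;
- **`adipoage.interaction`** — phenotype adjustment, BMI classification
  with (sex × age-year) frequency matching, the
  `adjusted BMI ~ age + PRS + PRS×age` Wald test, and a single-variant
  interaction scan behind a region/significance/clumping/open-chromatin
  filter cascade;
- **`adipoage.permutation`** — the random-gene-set permutation null for the
  regional PRS-age interaction, with empirical ranking.

The model at the core of the genetic half is the interaction regression

    adjusted BMI ~ age + PRS + PRS × age

where the PRS is a *regional* score built only from variants in the
±500 kb cis-windows of a gene set, fitted from GWAS summary statistics with
an L1 penalty: per LD block, coordinate descent solves
`w_j ← soft(r_j − Σ_{k≠j} B_jk w_k, λ)` with `B = (1−s)R + sI` and
`r_j = β_j/√(β_j² + (n−2)se_j²)`. The observed interaction Wald p is then
ranked against the same pipeline run on randomly drawn same-size gene sets.

See `docs/methods.md` for the generative models, parameter defaults and
numerical choices, and `examples/` for one narrative script per capability.

## Worked example

`examples/03_deconvolution.py` trains a reference on the default 40-donor
single-cell fixture, deconvolves noisy bulk mixtures, and compares ASPC
proportions young-vs-old within BMI strata:

```
mean |estimated - true| proportion error: 0.0051
    normal: young 0.220+/-0.025 (n=9)  old 0.174+/-0.010 (n=11)  W=96  p=0.0001
     obese: young 0.153+/-0.006 (n=11)  old 0.150+/-0.004 (n=9)  W=63  p=0.3312
```

The estimated proportions track the generating truth to half a percentage
point; the young-vs-old difference is significant among normal-BMI donors
(W is the Mann-Whitney statistic of the young group) and absent among obese
donors, who sit at the low ASPC level at every age — the fixture's planted
"obesity abolishes the age decline" structure.

`examples/05_prs_age_interaction.py` runs the genetic arm on a 2,400-person
synthetic cohort (half base GWAS, half test):

```
observed regional PRS x age interaction Wald p: 1.28e-09
planted gamma: -0.08
null permutations: 400  fraction with nominal p<0.05: 34.0%
percentile of observed signal: 99.0%  empirical p: 0.0125  significant (>95th): True
```

The regional score of the six target genes — whose cis-windows carry the
planted negative age interaction — ranks above the 95th percentile of
random same-size gene sets, so the interaction is specific to the target
set rather than generic to regional scores (random sets show elevated
nominal significance only because ±500 kb windows overlap the target
regions often on a 40-Mb toy genome).

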