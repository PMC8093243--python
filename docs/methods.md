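# Methods

## Scope and model overview

`cupsig` implements the computational core of a MEK-inhibitor
(trametinib) response-prediction workflow for poorly differentiated
metastatic tumours, together with the companion assay statistics used in
stem-like spheroid studies. Four analysis stages are chained:

1. **Expression processing.** Raw 3' tag counts are library-size
   normalised to CPM; genes are filtered (mean CPM < 5 plus
   duplicated-read percentage > 20% for QC of fresh quantifications;
   mean CPM < 1 for cohort analyses), replicates averaged, and profiles
   z-scored before ranking.
2. **Signature construction.** Across a cell-line panel with paired
   expression and drug AUC (area under the dose-response curve; lower =
   more sensitive), each gene's log-CPM is Pearson-correlated with AUC.
   The 1000 genes with the largest correlation are putative resistance
   markers; recursive feature elimination with a linear SVM
   (sensitive-vs-resistant extremes of the AUC distribution) reduces
   them to a 500-gene signature.
3. **Response calling.** A sample's genes are ranked from most to least
   expressed (z-scores) and the signature is scored with pre-ranked
   GSEA. Positive enrichment score (ES) with FDR < 10% calls the sample
   resistant, negative ES sensitive, anything else indeterminate.
4. **Assay statistics.** Single-hit limiting-dilution frequency with
   Wald CIs and likelihood-ratio comparison, 2^-ddCt copy-number calls,
   caliper tumor volumes and fold changes, viability normalisation.

## Enrichment score and its significance

The ES is the weighted Kolmogorov-Smirnov running-sum statistic with
weight exponent p = 1 (configurable): walking down the ranked list, a
set member adds `|stat|^p / sum_set |stat|^p` and a non-member subtracts
`1/(N - N_hit)`; ES is the signed extremum of the running sum. Because
the sum is piecewise linear between hits, extrema occur only at hit
boundaries; the production evaluator therefore works from sorted hit
positions in O(k) and is vectorised across permutations. The test suite
checks it against a literal O(N) walk and against an independent GSEA
implementation (gseapy) to ~1e-16. A tie between the positive and
negative extremum resolves to the positive one; ranking ties in the
statistic are broken by gene id, so runs are reproducible.

Significance uses a gene-label permutation null: the ES of `nperm`
random same-size sets on the same ranked list. The p-value is two-sided
on the magnitude with add-one smoothing,

    p = (1 + #{ |ES_null| >= |ES_obs| }) / (nperm + 1).

A same-sign-only count over an all-null denominator would double the
type-I error (each sign contributes its own alpha), while normalising by
the same-sign count alone changes the attainable floor; the magnitude
form is exactly uniform under the null — measured type-I error 0.047 at
alpha 0.05 over 2000 draws — and preserves the `1/(nperm+1)` floor. NES
divides ES by the mean |ES| of null draws sharing its sign; it is
reported, but calls use the permutation p with Benjamini-Hochberg
control (across a gene-set collection for signature scoring, across
samples for cohort calling — one test per sample for a single
signature). Significance thresholds are strict (`fdr < 0.10`). Genes of
a set absent from the profile are dropped and the used size reported;
phenotype permutation and adaptive multilevel p-value refinement are out
of scope. Default `nperm` is 1000 (raise to 10000 for publication-grade
p-value resolution; the floor at 1000 is 1e-3, far below the 0.1
threshold that drives calls).

## Expression processing choices

- **z-scoring axis**: per gene across samples (default). Ranking raw
  within-sample abundance would be dominated by constitutively high
  genes; standardising each gene first makes the rank reflect relative
  up/down regulation. Per-sample z-scoring is available as an option.
- **Variance denominator**: sample variance (n - 1), the cohort
  convention; documented so tests can assert exact values like
  `[1,2,3] -> [-1,0,1]`.
- **log transform**: log2(CPM + 1) before z-scoring and before the
  correlation screen (flag to disable); it stabilises the variance of
  count-derived values so a handful of high-count lines cannot dominate
  a Pearson correlation.
- **Zero variance**: constant genes are dropped with a warning at
  z-scoring and excluded from the correlation screen; a constant sample
  is an error.
- **Filter boundaries** are strict as printed: mean CPM < 5 removed
  (exactly 5 kept), dup% > 20 removed (exactly 20 kept), mean CPM < 1
  removed.
- Library-size normalisation is plain CPM; TMM-style compositional
  correction is a possible extension, not implemented.

## Signature construction choices

- "5%/95% quantiles" of the AUC distribution define the sensitive and
  resistant extremes, with linear-interpolation quantiles and inclusive
  boundaries (`<=` low, `>=` high); overlapping tails (degenerate
  response distributions) are an error.
- RFE eliminates `ceil(0.10 * current)` features per round (never
  overshooting the target), refitting a linear SVM (C = 1, balanced
  class weights) on per-round re-standardised features and ranking by
  |weight|. The schedule, C, and re-standardisation are fixed defaults
  exposed in the API; they favour reproducibility. Ties in |weight| are
  broken by gene id (larger id eliminated first), making the selection
  invariant to feature order. The final list is ordered by |weight|
  descending, but the signature is consumed as an unordered set by GSEA;
  order is metadata.
- When `target` equals the starting size the input is returned
  unchanged (no fit), honouring the no-elimination contract.

## Validation accounting

Truth labels on an IC50-annotated panel use "sensitive iff IC50 < 1 uM".
Indeterminate predictions count as errors for both classes — a
conservative choice that penalises abstention — and the reported average
accuracy is the macro average of the two per-class accuracies, so class
imbalance cannot inflate it.

## Limiting-dilution model

The single-hit Poisson form `P(positive | dose n) = 1 - exp(-f n)` is
fitted by maximum binomial likelihood via an intercept-only
complementary log-log GLM with offset `log n`; `f = exp(intercept)` and
the 95% CI is Wald on the log-frequency scale, exponentiated. The
Poisson form and `1 - (1-f)^n` agree to O(f^2). With a single dose the
MLE has the closed form `-ln(1 - p_hat)/n`; the GLM matches it to
< 1e-10 and the CI's empirical coverage at f = 0.01 (doses 10/100/1000,
24 wells each) is ~96% over 1000 simulations. Boundary data are not
extrapolated: all-positive plates leave f unbounded (error); all-negative
plates return f = 0 with a one-sided 95% upper bound
`-ln(0.05) / total cells` and a flag. Group comparison is a 1-df
likelihood-ratio chi-square of separate vs pooled frequencies,
symmetric in its arguments. Profile-likelihood CIs and multi-group
simultaneous fits are out of scope; excluding animals lost before the
endpoint is the caller's data-cleaning responsibility.

## Copy number and growth formulas

`ddCt = (Ct_target - Ct_norm)_sample - (Ct_target - Ct_norm)_calibrator`,
ratio `2^-ddCt`; a ratio of 1 indicates biallelic content and values
strictly below 0.7 are called allelic loss. Tumor volume is
`d^2 * D / 2` (minor axis d, major axis D, mm; swapped with a warning if
reversed), growth is expressed per animal as fold change vs the
baseline measurement, and viability is mean treated luminescence over
mean untreated control (warning below 6 technical replicates).

## Synthetic data: what it does and does not emulate

`simulate_ccl_panel` plants a latent per-line resistance score
r ~ N(0,1) that shifts marker-gene log2 expression by `beta * r` and the
AUC by `gamma * r`, both with independent Gaussian noise (default sd
0.5, the condition used throughout the validation suite; with
beta = gamma = 1 this gives cor(expression, AUC) ~ 0.8 for markers).
Baseline abundances are log-normal (mu ~ N(5,2) on the log2 scale) and
counts are one multinomial draw of 10^6 reads per line — so library
sizes are exact and dispersion is purely multinomial. Defaults (300
lines, 2000 genes, 100 markers) are the desk-scale stand-in for a
~445-line genome-wide panel; a `markers=` argument lets a held-out panel
share a training panel's generative process. `simulate_cohort` plants
+/-`effect` shifts of a signature on standard-normal z-like profiles;
`simulate_lda` draws binomial well outcomes under the single-hit model.

None of the generators reproduce real gene-gene correlation structure,
negative-binomial overdispersion, batch effects, or FFPE degradation.
Passing tests therefore demonstrate that the machinery recovers planted
structure under its own model assumptions — marker recovery, calibrated
error rates, CI coverage — not that the biological signature would
transfer to any particular external cohort.

## Problem sizes and numerical tolerances

The validation suite uses nperm = 199-500 permutations, 2000
calibration draws, 1000 coverage simulations, and 300/100/200-line
panels — sizes at which every stochastic check is stable under its
fixed seed. ES exactness is asserted at 1e-12 against the running-sum
oracle; the single-dose GLM at 1e-6 against the closed form; CPM column
sums and z-score moments at 1e-9 to 1e-12. All randomness flows through
`numpy.random.Generator` seeds; every simulation records its parameters
and seed.

## Known limitations

- Plain CPM (no TMM) and gene-label permutation GSEA only.
- The RFE hyperparameters cannot be checked against the original
  analysis (not reported there); results are reproducible, not
  necessarily identical to any prior run.
- Wald CIs on log f degrade for tiny positive-well counts (coverage is
  validated only at the simulated conditions above).
- Reproducing the external-cohort headline numbers (panel of 634
  IC50-annotated lines; archival tumour cohorts) requires third-party
  portal downloads and is out of scope here.
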