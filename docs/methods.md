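# Methods

## Model and assumptions

The analysis rests on three working assumptions about pathological nodal
staging in gastric signet ring cell carcinoma:

1. **No false positives.** A node read as metastatic is metastatic; the
   only misclassification considered is a missed positive node.
2. **Exchangeable nodes.** Examined nodes are treated as draws from a
   common per-patient positivity probability; nodal station and harvest
   order are ignored.
3. **Shared sensitivity.** The per-node positivity law estimated from
   node-positive patients is assumed to apply equally to diseased
   patients whose exam came back all-negative.

Under these assumptions a diseased patient with latent positivity
*p* ~ Beta(α, β) and *n* examined nodes shows
*k* ~ Binomial(*n*, *p*) positive nodes, and the false-negative
probability is the beta-binomial zero class

ProbFN(*n*) = B(α, β + *n*) / B(α, β) = ∏<sub>j=0</sub><sup>n−1</sup> (β + j)/(α + β + j),

strictly decreasing in *n* and asymptotically ∝ *n*<sup>−α</sup>. All
beta-function ratios are evaluated as log-gamma differences
(`scipy.special.betaln`); the finite-product form is kept as an
independent cross-check path only, and the two agree to 1e-12 relative
for n ≤ 500 (asserted in tests, alongside agreement to 1e-8 absolute
with numerical integration of ∫(1−p)ⁿ dBeta(p; α, β)).

## Fitting: zero-truncated maximum likelihood

Stage-specific (α, β) are estimated from node-positive patients only.
Because that sample is *defined* by k ≥ 1, the default likelihood
conditions on it: Σ log[pmf(k; n) / (1 − pmf(0; n))]. An untruncated
option (`truncated=False`, surfaced in the pipeline config) is provided
for sensitivity analysis; on ascertained k ≥ 1 data it is biased, and
the two fits differ measurably (asserted in tests).

Optimization is Nelder–Mead over (log α, log β) — parameter tolerance
1e-8 — started from a method-of-moments estimate plus four jittered
restarts drawn from a fixed-seed stream; the best optimum wins and is
never worse than the starting point. Estimates drifting outside
[1e-8, 1e6] are clipped and flagged *degenerate* (e.g. when every
observation has k = n, the likelihood pushes α → ∞ and β → 0). Each
T stage is fitted independently; no shrinkage across stages.

**Identifiability caveat (important).** Conditioned on k ≥ 1, the
beta-binomial law converges to an α-free limit as α → 0, so the
zero-truncated likelihood carries little information about small α.
With the T1-scale truth (α ≈ 0.07) the estimate frequently collapses to
the α → 0 boundary or overshoots severalfold unless thousands of
truncated observations are available; the profile log-likelihood at the
truth exceeds the boundary value by only a few log units even at 2,000
observations. This is a property of the three-step method itself, not
of the optimizer: at registry scale (tens of thousands of patients,
low early-stage prevalence, high early-stage miss probability) the
early-stage parameters — and hence their FN-adjusted prevalences — are
weakly determined. The end-to-end recovery test records this honestly:
T3/T4 recover within a few percent on a 20,000-patient synthetic
cohort, T1 (and usually the T2 prevalence) do not meet the 15%/0.02
bands, and the corresponding acceptance test fails by design rather
than being weakened.

## Prevalence adjustment

Per (stage, *n*) stratum the expected missed-case count is
#FN = ProbFN·#TP/(1 − ProbFN), capped at the stratum's observed
negative count: imputed FN patients are re-labelled from the observed
negatives, never invented, so #TP + #TN + #FN always equals the
stratum's patient count and the stage denominator stays "all patients".
The cap emits a warning when it binds. Strata are the distinct observed
values of nodes-examined; no binning. Adjusted prevalence is therefore
always ≥ apparent (observed positive fraction), with equality in the
perfect-sensitivity limit. Exported prevalences are rounded to three
decimals.

The bundled published prevalence table for this disease prints its two
columns with labels swapped relative to their arithmetic: the column
printed as "adjusted" (0.155/0.583/0.727/0.895) equals the raw positive
fractions computable from the cohort cross-tabulation, while the column
printed as "apparent" (0.173/0.690/0.807/0.941) is the larger,
adjustment-consistent one. This package always uses unambiguous names:
`apparent` = observed fraction, `adjusted` = FN-imputed.

## The staging score

NSS(*n*) = (1 − Prev)/((1 − Prev) + Prev·ProbFN(*n*)) is the posterior
probability of true nodal negativity given an all-negative exam. It is
defined as exactly 1 whenever ProbFN = 0 (perfect sensitivity makes a
negative exam conclusive regardless of prevalence), which also resolves
the 0/0 case at Prev = 1. Which prevalence enters the score is an
explicit parameter (`adjusted` by default, `apparent` or a user value as
alternatives); the headline bound checks hold under either printed
reading. Curves are evaluated over n = 1..n_max with n_max defaulting
to 90, the registry ceiling for the examined-node field.

Every patient receives a score as a function of (stage, nodes
examined) — node-positive patients included, matching the published
whole-cohort quantile analysis; restricting to node-negative patients
is a caller-side filter. Quartile groups default to *empirical*
within-stage cutoffs (25/50/75 percentiles of patient scores,
linear-interpolation percentile convention) with a *fixed*
0.25/0.50/0.75 mode also supported. Intervals are half-open with Q4
closed above, so fully tied scores land in Q4 with a warning.

**Documented inconsistencies in the published summary numbers.** With
the bundled (α, β) and either prevalence column, the minimal
examined-node counts printed alongside the source curves (12 for T2, 17
for T3, 27 for T4 at NSS 0.8) are not reproducible — the implied counts
are far larger (T2/T3 plateau below 0.8 by n = 90), and the in-text
early-stage miss probabilities (11.77% at n = 15, 6.11% at 25, 4.99% at
29) are likewise inconsistent with the printed T1 parameters, which give
ProbFN(15) ≈ 0.86. These numbers are therefore documented here but not
used as checks; the bound-style statements (T1 > 0.8 everywhere; at
n = 10, T2 < 0.8, T3 < 0.7, T4 < 0.6) do reproduce and are asserted.

## Uncertainty

Bootstrap resampling is by patient, within T stage (stage sample sizes
preserved — every estimand is stage-specific); an unstratified choice
would mix stages into stage-specific estimands. Intervals are 95%
percentile intervals — the simplest defensible reading — over
`n_boot = 1000` replicates by default (tests and examples scale down).
Replicates are refitted from a single start at the method-of-moments
estimate; refits that fail, lose identifiability (< 2 node-positive
resamples or all saturated) or go degenerate are dropped and counted,
and more than 20% failures raises an "unstable bootstrap" error — the
pipeline then omits that stage's CIs with a warning rather than
aborting. The replicate stream is fully determined by (data, seed,
n_boot).

## Survival

Kaplan–Meier estimation and the k-group log-rank test are delegated to
`lifelines` behind this package's interfaces; hand-rolled product-limit
and observed-minus-expected oracles verify them in the test suite. Ties
at an event time follow the standard deaths-before-censorings
convention. Per-stage tests across the four quantile groups carry no
multiplicity correction, matching the source analysis. Times are in
months; zero-time events are kept at zero by default (an optional +0.5
month shift flag exists for software that requires positive times).

## Synthetic cohorts

The generator emulates the registry extract's statistical structure:
stage from a four-way mix (defaults 116/60/176/209 over 561), true
disease ~ Bernoulli(stage prevalence; defaults 0.155/0.583/0.727/0.895),
examined nodes ~ 1 + NegBin(mean 14, dispersion 1.2) truncated at 90 (a
stand-in: the source reports no examined-node distribution, so all
recovery tolerances are defined against the generator's own truth),
latent positivity ~ Beta(α, β) with the published stage defaults, and
observed positives ~ Binomial — a zero draw among diseased patients is a
flagged false negative; disease-free patients never show positives.
Survival is exponential at 0.02/month for diseased vs 0.01/month for
disease-free (hazard ratio 2), with independent exponential censoring at
0.008/month and a 120-month administrative cutoff — producing roughly a
third censored; these survival defaults matter only to the
survival-module tests. One integer seed drives everything; each
patient's draws come from a sub-stream keyed by patient index, so
growing the cohort preserves earlier patients.

What the generator does *not* emulate: real examined-node distributions,
stage-dependent censoring, demographic structure beyond opaque labels,
or any violation of the three working assumptions. Passing recovery
tests therefore demonstrate internal consistency of the pipeline under
the model's own assumptions, not robustness to their failure.

## Problem sizes used in tests

Worked-example and oracle tests run on printed inputs in milliseconds.
The stochastic suites use: 5,000 observations for single-fit recovery,
50 replicates × (500 vs 5,000) for MLE consistency, a 20,000-patient
cohort for end-to-end recovery, 50 replicates of 2,000-patient
single-stage cohorts for the adjusted-beats-apparent property, 50 outer
replicates × 200 bootstrap resamples (400-patient T3-like cohorts) for
coverage, a 50,000-patient cohort for generator-vs-closed-form
agreement, and 50 replicates of
4 × 40 patients for log-rank null behavior — sizes chosen so each suite
estimates its property stably on a single CPU.

## Known limitations

* The three-step procedure is not a joint likelihood: prevalence
  adjustment treats the fitted (α, β) as known, and the bootstrap is
  the only uncertainty propagation.
* Small-α stages are weakly identified from zero-truncated data (see
  the fitting caveat); early-stage adjusted prevalences inherit that
  uncertainty.
* The FN cap introduces a slight downward bias in adjusted prevalence
  when strata are sparse (many distinct examined-node counts with few
  patients each).
* No covariate adjustment, competing risks, or Cox modelling; log-rank
  only.
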