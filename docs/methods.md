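# Methods

This note records the statistical model, the numerical choices, and
the reasoning behind the design decisions in `pbsample`, in the order
the pipeline applies them.

## Data model and censoring

A record is one first-draw tap sample: a concentration in ppb, a
censoring flag, and the reporting limit (RL) of the laboratory that
analysed it. Because several laboratories with RLs from 1 to 4 ppb
analyse samples within one program, a dataset is *multiply*
left-censored: each nondetect is informative only relative to its own
limit. All log-scale work uses the natural log; the data format and
summaries are always back-transformed to ppb.

Synthetic records retain the latent `true_value` alongside the
censored report so parameter-recovery tests can compare estimates
against the generating truth; file writers strip it by default.

## ROS imputation

Imputation follows the semiparametric ("robust") regression on order
statistics for multiply censored data:

1. **Plotting positions.** Sort the distinct censoring thresholds
   `L_1 < … < L_m`. The probability of exceeding threshold `L_j` is
   computed by the descending recursion
   `pe_j = pe_{j+1} + A_j/(A_j+B_j) · (1 − pe_{j+1})`, where `A_j`
   counts detects in `[L_j, L_{j+1})` and `B_j` counts observations
   known to lie below `L_j`. Detects in an interval get Weibull-type
   positions `(1−pe_j) + r/(A_j+1)·(pe_j − pe_{j+1})`; nondetects at a
   limit are spread uniformly over `(0, 1−pe_j)`. With no censoring
   this collapses to `r/(n+1)`. Ties among detects are broken by
   stable input order, which moves positions only at O(1/n).
2. **Regression.** OLS of `ln(detect)` on `z(position)`; censored
   records receive `exp(intercept + slope·z(position))`. Detects are
   never altered — the fitted line fills in only the censored mass, so
   a poor distributional fit in the tail cannot distort observed data.
3. **Clamp rule.** When the fitted line would impute a value at or
   above the record's own RL (possible when detects far above the
   limit dominate the regression), the value is clamped to
   `0.999 · RL` with a warning, preserving below-limit semantics. The
   choice of 0.999 is arbitrary within (0, 1) and documented so tests
   are exact.

`fit_lognormal_mle` then estimates `mu` as the mean of logs and
`sigma` with the n−1 denominator (pinned so small closed-form examples
are exact). Normal-theory standard errors `sigma/√n` and
`sigma/√(2(n−1))` are attached; they ignore imputation uncertainty and
understate the spread under heavy censoring — a documented limitation,
not corrected in v1.

Alternatives deliberately not implemented: substitution (RL/2) and a
fully parametric censored likelihood (Tobit-style). The
imputation-first route was chosen because the downstream mixture EM
operates on complete data; a censored-likelihood EM is a declared
non-goal.

## Goodness of fit

The one-sample KS statistic compares log values against the fitted
normal. Since the parameters were estimated from the same data, the
classical KS null distribution is invalid; the p-value comes from a
parametric bootstrap *with refitting* (default 500 replicates, seeded).
Every result carries a caveat string: samples from one program share
temporal and spatial structure, so independence-based p-values are
broad-scale indications, not precise probabilities.

## Mixture model

Community-wide data mix homes with and without lead plumbing, so a
single log-normal often fits poorly. `fit_mixture_em` runs standard
Gaussian-mixture EM on the logs of the ROS-completed values:

- **Initialisation.** Default `quantile_split` seeds the upper
  component from the right tail (split at the 90th percentile of logs
  for k=2; at the 80th/95th for k=3), reflecting the long-right-tail
  structure of tap-lead data; `random` initialisation supplies restart
  diversity.
- **Convergence.** Stop when the relative log-likelihood improvement
  falls below 1e-8 or at 1000 iterations; the likelihood is
  non-decreasing by the EM guarantee and the per-iteration trace is
  kept for verification. Non-convergence is reported via
  `converged=False`, never an exception.
- **Degeneracy.** A variance floor of 1e-6 (log scale) and a minimum
  effective component occupancy of 2 observations guard against
  component collapse; a collapsed run restarts from a fresh random
  seed (up to 5 retries) before raising.
- **Labelling.** Components are always relabelled ascending in `mu`,
  so "component 1" is the low-concentration majority regardless of
  initialisation order.
- **Selection.** `select_k` fits each candidate k with 10 restarts
  (first quantile-split, rest random, seeds spawned from the master
  seed) and returns the minimum-BIC model with the full BIC table,
  `BIC = −2·loglik + (3k−1)·ln n`.

With k=1 the EM fixed point is the closed-form Gaussian MLE with the
n denominator — one documented denominator difference from
`fit_lognormal_mle`'s n−1.

Identifiability caveat: when components overlap heavily (e.g. a 5%
minority under a wide majority), component means carry intrinsic
sampling error of order 0.15 log-units at n≈5000 and BIC may prefer
k=1 at moderate n; the test suite asserts only what is statistically
stable (weight recovery, selection consistency for well-separated
mixtures).

## Compliance statistic and Monte Carlo

The regulatory count-up 90th percentile sorts a round ascending and
takes the value at rank `r = 0.9·n`; censored values enter at their
reporting limit (an upper bound, independent of any imputation). The
regulation's text covers integer ranks only; for fractional `r` this
package linearly interpolates between the bracketing order statistics
by default and ships a strict `round_up` mode for sensitivity checks.
At the standard round size n=150 the two modes coincide (the 135th
order statistic). A round exceeds the action level when its p90 is
*strictly* greater than 15 ppb.

The Monte Carlo analysis draws `n_draw=150` concentrations per
replicate from a fitted mixture, computes the count-up p90, and
repeats `n_rep=10000` times. For a single log-normal component the
chain has a closed-form check: the p90 of a round exceeds a threshold
`x` iff at least 16 of 150 draws do, so the exceedance probability is
the binomial tail `P(Bin(150, 1−F(x)) ≥ 16)` — used as an end-to-end
oracle in the tests.

## Grouping and comparisons

Treatment grouping splits records at the introduction of
orthophosphate corrosion control (April 2019). Records whose timing
relative to the change cannot be confirmed are excluded: regulatory
rounds reported June 2019 (collected January–May 2019) and
customer-requested samples analysed April–May 2019. Customer records
are grouped by analysis date, accepting the known edge effect that
late-December collections may be analysed in January. Two-sample
comparisons (KS, Wilcoxon rank-sum) run on ROS-imputed values by
default and are two-sided; the rank-sum test uses midranks with the
tie-corrected variance
`n1·n2/12 · [(N+1) − Σ(t³−t)/(N(N−1))]`, which is exactly the
permutation variance of the midrank statistic (heavy ties arise from
values parked at reporting limits). No multiple-testing correction is
applied to pairwise matrices — reported p-values are raw.

## ZIP-level self-selection

Customer programs over-represent neighbourhoods where lead is salient.
The assessment aggregates records per ZIP (`frac_above_rl`,
`frac_sampled = n_samples/n_homes` against an input housing-count
table) and fits unweighted OLS of `frac_sampled` on
`(1, x, x²)`; a weighted (by sample count) mode sits behind a flag.
Repeat samples from one street block are counted separately: with
block-level anonymisation, home identity is unknowable, so
de-duplication would be guesswork. Geocoding, census retrieval, and
spatial autocorrelation statistics are out of scope.

## Synthetic generator

The generator produces the structure the analysis assumes — not a
spatial or temporal replica of any real utility:

- concentrations from a k-component log-normal mixture; per-record
  reporting limits drawn from a schedule `{(RL, fraction)}` emulating
  multiple laboratories (defaults put 85% of records at 1 ppb, 10% at
  2 ppb, 5% at 4 ppb); censoring applied against each record's own
  limit;
- `pre_ortho` preset: weights 0.95/0.05, component 1 calibrated from
  the CDF anchors (0.49 at 1 ppb, 0.90 at 6.47 ppb) ⇒
  `(mu, sigma) ≈ (0.036, 1.429)`, component 2 from its 90th percentile
  of 17.9 ppb with `sigma = 1.0`; cohort size 12000;
- `post_ortho` preset: weights 0.60/0.40, component 1 from
  q90 = 1.0 ppb with `sigma = 1.4289`, component 2 from q90 = 13.1 ppb
  with `sigma = 1.0`; cohort size 2000.

Only one quantile of each singly-anchored component is published, so
their dispersions are calibration choices: component 2 takes
`sigma = 1.0` (a Tier-I-like population is more homogeneous than the
community at large), and the post-treatment component 1 reuses the
pre-treatment majority dispersion 1.4289 (treatment shifts the level
much more than the spread). Cohort sizes approximate the emulated
programs (~13k samples pre-treatment, ~2k post).

The ZIP cohort generator pins each ZIP's above-detection share `e`
exactly (`mu_z = ln RL − z(1−e)·sigma`) and samples
`Binomial(n_homes, π(e))` homes with the quadratic link
`π(e) = c0 + c1·e + c2·e²` clipped to (0, 1]; a flat link gives
unbiased sampling, an increasing link reproduces self-selection.

What the generator does **not** emulate: seasonal structure, temporal
autocorrelation, repeat sampling of the same home, spatial layout and
service-line inventories, or laboratory measurement error beyond
censoring. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed mixture-with-censoring model,
not robustness to those real-data features.

## Determinism and seeding

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from the single config seed via `SeedSequence.spawn`,
so identical config + seed reproduces byte-identical numeric outputs,
and the run manifest records the seed, config hash, and derived stage
seeds.

## Problem sizes in the checks

The statistical acceptance checks use 10,000 Monte Carlo replicates of
150 draws (the emulated compliance design), 200 cohorts of n=500 for
ROS recovery, n=5000 for EM weight recovery, and 100 trials per
direction at n=2000 for BIC selection consistency — sizes at which the
asserted tolerances have comfortable statistical margins while the
whole suite runs in a few minutes.
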