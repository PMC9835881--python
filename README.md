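# pbsample

Censoring-aware statistics for drinking-water lead sampling programs.

Utilities monitor lead at consumer taps under the Lead and Copper Rule
(LCR): a compliance round samples ~100–180 targeted Tier I homes (known
lead service lines or lead plumbing), and corrective action is required
when the round's **count-up 90th percentile** exceeds the 15 ppb action
level. Alongside, some utilities run customer-requested sampling
programs open to any home. Both kinds of data are heavily
**left-censored** — laboratories report many samples only as "below the
reporting limit" (BRL), with limits varying from 1 to 4 ppb across
laboratories — and customer-requested data mix two very different home
populations: a low-lead majority and a minority resembling Tier I
sites. `pbsample` provides the statistical machinery to analyse such
programs, and a seeded synthetic generator so every stage is testable
without any data download.

## What it computes

- **ROS imputation** (`pbsample.censored`). Semiparametric regression
  on order statistics for multiply left-censored data: plotting
  positions from the multi-limit threshold recursion, OLS of
  log-detects on normal quantiles, imputation of each nondetect from
  the fitted line at its own position (`exp(b0 + b1 z(p))`); observed
  detects are never altered. Exposed as
  `CensoredLognormal(dataset).fit()` → results with `(mu, sigma)` on the
  natural-log ppb scale, standard errors, the imputed dataset, and a
  parametric-bootstrap Kolmogorov–Smirnov goodness-of-fit test.
- **Log-normal mixtures** (`pbsample.mixture`).
  `LognormalMixture(values, k).fit()` runs EM on the log scale
  (k ∈ {1,2,3}); model order is chosen by BIC
  `= −2·loglik + (3k−1)·ln n`. Results carry component weights,
  `(mu_j, sigma_j)`, component and mixture quantiles
  `exp(mu_j + z(p)·sigma_j)`, and the BIC table.
- **Compliance statistics** (`pbsample.compliance`). The regulatory
  count-up 90th percentile (sort ascending, rank `0.9 n`; censored
  values enter at their reporting limit) and Monte Carlo exceedance
  analysis: draw 150 values from a fitted mixture, compute the count-up
  p90, repeat 10,000 times, and report `P(p90 > 15 ppb)`.
- **Comparisons** (`pbsample.comparisons`). Annual and
  pre/post-treatment grouping (orthophosphate corrosion control,
  April 2019, with the timing-unconfirmed exclusions), two-sample KS
  and tie-corrected Wilcoxon rank-sum tests, pairwise test matrices.
- **Self-selection assessment** (`pbsample.spatial`). ZIP-level
  aggregation of sampling intensity and above-detection fractions, and
  the quadratic OLS trend of `frac_sampled` on `frac_above_rl`.
- **Synthetic programs** (`pbsample.synthetic`). Seeded cohorts from a
  two-component log-normal mixture with per-record reporting limits,
  calibrated presets for the pre/post-treatment periods, and
  ZIP-structured cohorts with a quadratic self-selection link.

## Worked example

```python
import pbsample as pb

cohort = pb.generate_cohort(pb.preset("post_ortho", seed=42))
print(f"{len(cohort)} records, {cohort.n_censored} below reporting limit")

res = pb.CensoredLognormal(cohort).fit()
print(res.summary())

mix = pb.LognormalMixture(res.imputed_dataset.values, k=(1, 2)).fit(seed=0)
print(mix.summary())

curve = mix.simulate_compliance(pb.MonteCarloConfig(n_draw=150, n_rep=10000, seed=1))
print(f"P(count-up p90 of a random 150-home round > 15 ppb) = "
      f"{curve.exceedance_probability(15.0):.4f}")
```

prints

```
2000 records, 1197 below reporting limit
Censored log-normal fit (semiparametric ROS)
================================================
n                                           2000
censored (BRL)                        1197 (59.9%)
reporting limits (ppb)           [1.0, 2.0, 4.0]
mu (log ppb)                        0.0186 (se 0.0332)
sigma (log ppb)                     1.4847 (se 0.0235)
fitted median (ppb)                        1.019
fitted p90 (ppb)                           6.830
count-up p90 (ppb)                         7.354

Log-normal mixture (k=2), EM on the log scale
========================================================
n = 2000   loglik = -3614.274   BIC = 7266.552
converged = True in 269 iterations
comp     weight        mu    sigma    median       p90
1        0.8708   -0.2838   1.3211     0.753     4.093
2        0.1292    2.0563   0.7219     7.817    19.716
BIC table:
 k       loglik         bic  converged
 1 -3627.802267 7270.806339       True
 2 -3614.273649 7266.551811       True

P(count-up p90 of a random 150-home round > 15 ppb) = 0.0000
```

Reading the output: 60% of the synthetic post-treatment cohort is
below its reporting limit; after ROS completion the single log-normal
puts the community-wide 90th percentile near 6.8 ppb, well under the
15 ppb action level. BIC prefers two components: a low majority
(median 0.75 ppb) and a high minority whose 90th percentile
(~20 ppb) resembles a Tier-I-like population. Even so, a randomly
drawn 150-home compliance round essentially never registers an
action-level exceedance — random community sampling is insensitive to
the regulatory statistic that targeted Tier I sampling is designed to
probe.

A command-line interface mirrors the library
(`pbsample simulate|impute|fit|mc|report|run`); `pbsample run --config
cfg.yaml` executes the whole pipeline and writes per-group summaries,
fits, exceedance curves, test matrices, and a reproducible run
manifest.

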