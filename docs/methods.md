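# Methods

This note documents the models, calibrations and design choices behind
`mhbrain`: what the synthetic-data generator emulates and how its planted
quantities are made exact, how each analysis stage is defined numerically,
and what passing the test suite does and does not establish about real data.

## The synthetic cohort generator

### Latent structure

Each subject carries a scan-day affect state `z ~ N(0, 1)`. Everything the
pipeline is meant to detect flows through `z`:

* **Items.** Each questionnaire's effective state is
  `z_eff = √(1−s)·b + √s·u`, where `b` is the timing-appropriate affect
  state, `u` a stable scale-specific factor and `s = 0.3` its variance
  share. For online instruments (PHQ-9, GAD-7), `b = z_online`, which
  correlates with `z` at `w = 0.7 + 0.3·exp(−|latency|/600 d)` — the
  questionnaire latency is drawn uniformly on −1,185…+964 days, so
  same-day instruments agree more than instruments acquired years apart.
  Item propensities `λ·z_eff + √(1−λ²)·ε` (λ = 0.80 RDS-4, 0.75 PHQ-9/
  GAD-7, 0.65 N-12) are cut at the normal quantiles of right-skewed level
  probabilities (e.g. 0.55/0.25/0.12/0.08 for the four RDS-4 levels),
  reproducing the floor-heavy score histograms of population samples.
  Under the defaults this yields Cronbach's α ≈ 0.83 for RDS-4,
  cross-scale Spearman correlations of ≈ 0.45–0.57, and a two-year RDS-4
  rank stability of ≈ 0.55 (the timepoint-2 affect state correlates with
  timepoint 1 at 0.6).
* **Depression fields.** Lifetime-occurrence, episode-duration and
  help-seeking fields are Bernoulli/geometric draws whose probabilities
  increase in `z`; probable depression status is *derived* from them by the
  scoring rule, and the "seen GP" field doubles as the case label for
  matching (case prevalence ≈ 30%).
* **IDPs.** 126 IDP columns span eleven modality tags (network amplitudes,
  full/partial network edges, volumes, areas, thickness, FA, MD, T2*, WMH,
  task activation). Each modality has `max(1, n/8)` shared factors carrying
  `factor_variance_share = 0.5` of every IDP's variance — the within-
  modality correlation real IDP families show — plus unique noise. The
  affect signal enters *through the factors* (`F_f = a_f·z + noise`), i.e.
  the brain-behavior mode is low-rank and lives in the high-variance
  subspace, which is both the realistic situation and the reason
  modality-wise PCA retains it.

### Exact calibration of the planted canonical correlation

Because `z` is the only path connecting the blocks, the population
canonical correlation factorizes as `r = ρ_X · ρ_Y`, where `ρ_Y` is the
best linear alignment of the five summary scores with `z` and `ρ_X` the
same for the IDP block.

* `ρ_Y` is estimated once from a 100,000-subject calibration draw under a
  fixed internal seed (the discretized items make a closed form
  impractical); it is ≈ 0.854 under the defaults and identical across user
  seeds.
* `ρ_X` has a closed form under the factor model: with factor signal
  `a_f = α·c_f`, loading `l² = 0.5` and `n_f` IDPs per factor, the Fisher
  information is `t(α) = Σ_f (a_f l)² n_f / ((1−l²) + n_f l² (1−a_f²))`
  and `ρ_X² = t/(1+t)`. The scale `α` solves `ρ_X = effect_r / ρ_Y` by
  Brent's method; configurations that cannot reach the requested
  `effect_r` (including `effect_r ≥ ρ_Y`) are rejected.

Per-modality effect weights redistribute `c_f` so that planted modality
importance can be varied; the default is uniform.

### Test–retest structure

Timepoint-2 IDPs share a stable subject component with timepoint 1. The
`z`-signal is treated as trait-like (fully stable); the remaining factor
and unique noise splits into stable and transient parts with per-factor
share `λ_f = (ρ_m − a_f²l²)/(1 − a_f²l²)`, which makes the test-retest
correlation of every deconfounded IDP equal its modality target `ρ_m`
exactly. Defaults follow the structure-above-function pattern of imaging
reliability studies (volume/area 0.85 … task 0.35). The inter-scan
interval is `N(824, 45)` days, independent of the IDPs, so
interval-adjusted ICCs should (and do) barely move.

Confound effects — site (3 levels), age, sex, head size, both motion
parameters, date — are added to IDPs with coefficients drawn once under a
fixed internal seed (`σ_β = 0.075`, ≈ 4–5% of IDP variance, the magnitude
reported for the standard confound set). Missing cells are MCAR at 1% in
structural/task columns only, at positions shared across timepoints.

### What the generator does not emulate

Non-Gaussian IDP marginals, site-by-age interactions or any structured
(non-MCAR) missingness; genuinely trait-stable neuroticism (N-12's
two-year stability is generated like RDS-4's, lower than real panel data
show); selection effects in who completes the online questionnaire; and
any spatial or temporal structure inside the imaging data itself (IDPs are
summary scalars by definition). Passing tests therefore demonstrates the
*statistical machinery* — calibration, leakage-free replication,
reliability estimation — not robustness to every real-data pathology.

## Analysis stages

* **Scoring** propagates any missing or out-of-range item to a missing
  score; nothing is imputed at the item level, so the cohort filter sees
  true missingness. "Prefer not to answer" style codes are treated as
  missing. Duration "at least 1 week" is `≥ 1` on the numeric weeks field.
* **Cohort.** Exclusion precedence is motion, then missing mental health,
  then late onset. Matching is greedy in seeded random order; age matching
  is exact in integer years (a tolerance parameter exists), and |Δ motion|
  ties break on the smallest subject id for determinism. The split is at
  pair level, `floor(2/3 · n_pairs)` exploratory.
* **Residualization** fits each variable separately by least squares on
  the full-rank confound design (site one-hot with reference level
  dropped; age and date centred before squaring and interacting; date in
  days since the sample's earliest scan), skipping rows with missing cells
  for that variable. The confound model is refit within each analysis
  sample (exploratory, confirmatory, retest at each timepoint) — unlike
  the PCA/CCA weights, confound betas are never transferred.
* **Imputation** fills a missing cell with the mean of its variable over
  the k = 1 nearest subjects, distance = Euclidean over variables observed
  in both rows within the same modality block.
* **PCA** standardizes variables and keeps the minimal component count
  reaching 50% cumulative explained variance per block; the largest-|loading|
  entry of each component is made positive so projections are
  deterministic. Held-out data is projected with stored means, scalings
  and loadings — never refit.
* **CCA** whitens each block by SVD (raising a named error on rank
  deficiency) and takes the SVD of the whitened cross-covariance, so
  canonical-score orthogonality is exact; the largest-magnitude Y-side
  coefficient of each mode is made positive. Permutation inference
  shuffles both blocks' row order independently; because row shuffles
  leave each block's covariance (hence whitening) unchanged, the permuted
  canonical correlations are exactly the singular values of the permuted
  whitened cross-covariance — an equivalence the suite verifies against an
  explicit refit. p-values use the add-one formula `(1 + #{r* ≥ r})/(1 + B)`
  and can never be zero.
* **Averaged-UV loadings.** U and V are z-scored before averaging so the
  block with larger score variance cannot dominate; the loading of an IDP
  is its Pearson correlation with that average (pairwise-complete rows).
* **Replication** p-values are parametric (t-test on the held-out
  correlation, Bonferroni-corrected by the number of modes): the held-out
  correlation is not a maximized statistic, so the permutation machinery
  is unnecessary there. Post-hoc interpretation of weaker modes is left to
  the analyst; the model reports all modes.
* **Equipercentile linking** uses the mid-percentile-rank convention
  (`100·(P(X<s) + P(X=s)/2)`, equivalently the continuized CDF with score
  `s` occupying `[s−0.5, s+0.5)`), inverts the target's continuized CDF by
  linear interpolation over the full integer grid (zero-frequency scores
  appear as flat segments) and clamps to the attained target range. No
  presmoothing is applied — the intended samples are large.
* **ICC(A,1)** comes from the two-way ANOVA mean squares
  `(MSR − MSE)/(MSR + MSE + (2/n)(MSC − MSE))`; covariate-adjusted
  variants residualize the covariate (with intercept) out of each
  timepoint's values — a configurable switch restricts this to one
  timepoint — and a constant covariate is a no-op rather than a recentring.

## Problem sizes and numerics

The validation studies run at desk scale, chosen to keep Monte-Carlo error
comfortably inside the asserted tolerances: planted-mode recovery uses 20
seeds of n = 2,000 training / 1,000 held-out subjects with the 126-column
brain block (mean r₁ within ±0.05 of the planted 0.3); permutation
calibration uses 200 null repeats at n = 500 with 500 permutations
(rejection rate inside the exact binomial 95% band [0.024, 0.087]);
reliability recovery uses a 625-subject retest sample. Oracle-equivalence
checks (Spearman, KS, Cronbach α, Cohen's d, ICC(A,1), kNN imputation
against loop-level brute-force reimplementations) are exact to 1e-10
relative tolerance. `sklearn`'s iterative CCA and `pingouin`'s ICC(A,1)
serve as additional independent cross-checks in the suite; the package's
own solver is the SVD formulation above.

## Known limitations

Training canonical correlations remain optimistic whenever the CCA input
dimension is non-negligible relative to n — the replication estimate is
the honest one, which is the package's central design point. The greedy
matcher is not optimal matching (a case can consume the control another
case needed); with realistic pool sizes this loses only a few pairs. The
equipercentile inverse is ambiguous across zero-frequency target scores
(the flat-segment convention picks the left edge). ICC adjustment by
regression assumes a linear covariate effect.
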