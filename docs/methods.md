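# Methods

## The index

For one trait at one time point, plasticity is quantified between the
two condition groups with the greatest statistical difference:

```
*ESPI = |g| / D,      g = d · J(v),      d = (x̄₁ − x̄₂) / S_pooled
```

`S_pooled` uses `(nᵢ − 1)` weights and sample SDs with the n − 1
denominator throughout (anything else would make the weights
incoherent). `J(v)` is the exact Gamma-function unbiasing factor,
evaluated through log-Gamma so it is stable for any `v`; the rational
approximation `1 − 3/(4v − 1)` is offered for users who prefer it (the
two differ by < 5·10⁻⁴ from `v = 10` on). The library always computes
and reports the correction — "skip the correction for n₁+n₂ > 20" is a
presentation choice, not a different estimator, and a uniform output
schema is worth more.

`D` is the Euclidean distance between the two conditions after min–max
normalizing every environmental axis over the conditions *observed in
the loaded experiment* (not nominal design ranges — incubators drift,
and the observed labels are what the data support). Axes must be
numeric/interval-scaled; ordinal factors are rejected rather than
silently coded. Distances therefore live in `[0, √k]` for `k` axes, and
any cross-study comparison must quote `k` and the axis ranges; the
result writer stamps both into the output header for that reason.

Two magnitude conventions are deliberate:

- **|g| in the numerator.** Plasticity is a magnitude of response; the
  sign of g depends only on which condition is listed first. Signed g,
  its SE and its CI are retained in every result for inspection.
- **Screen annotates, never gates.** The Welch ANOVA + Games–Howell
  screen exists to *find* the most different pair (smallest post hoc
  p-value; ties broken by larger |statistic|, then lexicographic
  condition ids, so selection is deterministic). A non-significant
  screen is reported as such but does not block the computation.
  Games–Howell p-values are used raw: the studentized-range reference
  already controls the familywise rate across pairs.

## Uncertainty

The sampling distribution of the two-sample t statistic is noncentral
t; everything downstream follows from that.

- **Standard error.** `Var(g) = J² · v/(v−2) · (2/ñ) · (1 + δ²ñ/2) − δ²`
  with `ñ = 2n₁n₂/(n₁+n₂)` and the unknown population effect δ replaced
  by the observed g. This is the exact ("true") variance of g, valid
  for `v > 2`; at the true δ it matches the Monte-Carlo SD of g to
  within sampling error (checked at n₁ = n₂ = 10 over 10⁵ replicates).
- **Confidence interval.** Pivot inversion: find the noncentrality
  parameters that place the observed statistic `t = d·√(ñ/2)` at the
  α/2 and 1 − α/2 tail probabilities of the noncentral t with `v` df
  (via `scipy.special.nctdtrinc`, vectorizable and with no root-finding
  of our own), then divide by `√(ñ/2)` to return to the effect-size
  scale. This interval has exact coverage for the population effect
  (94.7% measured at the 95% level, δ = 0.5, n₁ = n₂ = 10, 2·10⁴
  replicates) and always brackets g. Inverting at `g·√(ñ/2)` instead —
  a reading the source notation permits — shifts coverage to ≈95.6%;
  the standard pivot was kept.
- **Index-scale CI.** The environmental coordinates are design levels,
  treated as known, so `1/D` is a fixed positive constant and the g-CI
  maps exactly onto the index scale (mirrored when g < 0). No interval
  is propagated for D itself.

The classical index `(X − x)/(E − e)` is included as the comparison
baseline and is deliberately left scale-dependent — that dependence is
the point being demonstrated.

## Screening statistics

Welch's heteroscedastic one-way F (Welch–Satterthwaite denominator df)
and Games–Howell (unequal-variance SEs, per-pair Welch–Satterthwaite
df, studentized-range reference with k groups) are implemented as
vectorized numpy/scipy kernels so that null-calibration studies with
10⁴ replicates stay fast; pingouin's implementations serve as the
independent oracle in the test suite, and Games–Howell additionally
reduces to Tukey HSD on balanced homoscedastic data within simulation
tolerance. For large null simulations, rejection at level α is decided
by comparing the q statistic with `studentized_range.ppf(1−α, k, df)`
interpolated monotonically over a df grid — exactly equivalent to
`p ≤ α` and orders of magnitude faster than evaluating each sf.

## The synthetic benchmark

`espi.simulate` regenerates an adversarial 10-group study meant to
stress the estimator, not to flatter it. Per group `i` (defaults in
parentheses):

- clean signal: log-normal with log-location spaced over groups
  (4.5 → 6.6, so true means span ≈ 95 → 1000) and log-SD growing with
  it (0.4 → 0.8) — larger-mean groups are noisier both relatively and
  absolutely, giving the mean–variance association real assays show;
- additive Student-t noise, df 3, scale 0.8 × the group's clean SD —
  heavy tails and the negative raw values a "log-normal" assay still
  produces once instrument error is added;
- symmetric point contamination (rates 2–8% by group, offset ±7 clean
  SDs) — outliers without biasing group means;
- missingness 8% MCAR on draws of 85–160 per group, leaving observed
  sizes ≈ 75–150, unbalanced;
- 10 environmental variables with uniform marginals through a Gaussian
  copula, block-correlated ρ = 0.7 within {z4,z5,z7}, {z1,z2,z8,z9,z10},
  {z3,z6} and independent across blocks.

**Ground truth** is the standardized effect of the *clean* signal:
`|μᵢ − μⱼ| / √((σᵢ² + σⱼ²)/2)` from the closed-form log-normal moments,
equal-weight pooling (population moments carry no sample size;
n-weighted pooling is available as an option). Noise, contamination and
missingness are nuisance processes the estimator must survive; because
they inflate the sample SD but not the truth, the estimated g is
attenuated, and multi-axis *ESPI shows a systematic negative bias — the
qualitative signature the benchmark is designed to exhibit. The noise
and contamination scales were fixed once so that the default
configuration shows this signature robustly (negative mean bias at ≥ 3
axes in ≳ 95% of seeds) alongside the raw-range, skew, size and
mean–variance patterns above, and are exposed in `SimConfig` for anyone
who wants a gentler or nastier world.

What the generator does *not* emulate: temporal autocorrelation across
days, condition-level pseudo-replication (plate effects), non-MCAR
missingness tied to culture collapse, and real covariance between trait
noise and environment. Passing the benchmark therefore shows robustness
to marginal messiness, not to structured experimental artifacts.

### Known structural fact about axis-count trends

With nested axis subsets (z1..zn, the convention adopted), adding an
axis adds a nonnegative term to D², so every pair's *ESPI is
non-increasing in the axis count. Consequently the bias decreases
monotonically with axes; once it is negative (from ~3 axes here), its
magnitude necessarily *grows* as axes are added. A claim that |bias|
shrinks from low to high axis counts while remaining negative cannot
hold under nested subsets and a common ground truth — the harness
reports the measured trend (|bias| and RMSE fall steeply from 1–3 axes
as small-denominator blow-ups disappear, then rise slowly from 5–10 as
the compression bias accumulates) rather than forcing one.

## Evaluation harness

- bias = mean(est − truth), RMSE = √mean((est − truth)²), with
  normal-approximation CIs over the 45 pairs; CV = 100·SD/|mean|
  (values here are nonnegative by construction; the absolute value
  guards degenerate inputs).
- Unit sensitivity rescales the raw data by 0.5/2/10: the classical
  index moves 1:4:20, *ESPI is unchanged to machine precision.
- Axis sensitivity fixes one pair (S1, S10 by default) and swaps the
  single denominator axis, on normalized axes so the spread isolates
  geometry; the 10-axis *ESPI is the reference row.
- Direction claims (dispersion reduction vs the classical index,
  systematic underestimation) are assessed over 100 generator seeds as
  pass fractions, because any single adversarial draw is noisy.
- The convex hull + centroid of per-day (|g|, D) points is a purely
  descriptive summary (shoelace centroid; collinear or < 3 points
  degrade to zero area with a flag).

## Day-by-day workflow and the time fit

Each trait × day cell is analyzed independently (no temporal smoothing);
cells that cannot be analyzed — all groups constant, or a selected pair
with coincident environments — produce a row with the failure reason
instead of aborting the run, since proceeding through non-significant
or degenerate cells is part of the method. The *ESPI-vs-day series can
be summarized by `a·exp(−(t−μ)²/(2σ²))` via least squares with
deterministic initialization (a₀ = max value, μ₀ = its day, σ₀ = half
the span; ≥ 4 time points required). A fitted width exceeding 10× the
observed span is flagged ill-conditioned (a constant series has no
peak); non-convergence raises an error carrying the initial values.

## Numerical and interface choices

- Zero pooled variance raises a typed degenerate-data error rather than
  returning infinity; batch drivers log and skip.
- Zero environmental distance likewise (same environment, different
  response — the index is undefined there by construction).
- Missing trait values are dropped per group before n is counted;
  n₁ ≠ n₂ is fully supported.
- All randomness in the generator flows from a single integer seed
  (`numpy.random.default_rng`); identical seed + config ⇒ bit-identical
  studies and byte-identical result files.
- Mahalanobis distance (covariance estimated from the experiment's
  normalized condition coordinates, pseudo-inverse for rank-deficient
  designs) is available behind a switch for users whose axes are
  strongly correlated; Euclidean remains the default and the reference.
- Test and calibration problem sizes (10⁴ CI-coverage replicates,
  10⁵ SE replicates, 100-seed direction studies, 10⁴-replicate null
  screens with k = 3, n = 10) were chosen as the smallest sizes at
  which Monte-Carlo error is comfortably below the tolerances being
  asserted.

## Limitations

- Repeated-measures / within-subject designs are out of scope; the
  day-by-day analysis treats days independently.
- Only numeric environmental axes are supported.
- *ESPI values computed with different axis counts are not directly
  comparable (distance grows with dimension); report the axis count.
- The multi-axis index underestimates the true standardized effect on
  noisy data — consistently, but no bias correction is applied.
- The empirical diatom case study's deposited dataset is not bundled;
  the pipeline accepts it as a tidy CSV once exported.
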