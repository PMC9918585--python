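# Methods

## Scope and model

The package answers design questions for experience-sampling studies of
momentary affect measured on a bounded slider (0–100).  Everything is built
around three computations:

1. **Measures.** Seven person-level statistics — mean, SD, relative SD,
   RMSSD, TKEO, PAC and the lag-1 autocorrelation — computed from a
   time-ordered report series.  All instability/inertia measures are
   *order-based*: any adjacent pair of retained reports counts as
   successive regardless of the elapsed time between them, including
   overnight and multi-day gaps.  This matches the formulas' definitions
   and means a subsampled series is scored exactly like an originally
   sparse one.
2. **Accuracy.** A person's "true" measure value is defined as the measure
   computed from their complete record (inclusion cut: ≥ 50 reports,
   configurable).  For a sampling strategy and a number of observations n,
   the person's error is the RMSE of subsample estimates against that
   truth; stochastic strategies are re-drawn (default 1000 replicates,
   reduced in desk-scale runs, always reported in the output), while close
   and distant selection are deterministic and contribute a single absolute
   error.  Person RMSEs are averaged with equal weight per person,
   with a percentile-bootstrap CI (default 2000 resamples) over persons.
3. **Power.** Monte-Carlo power for a two-tailed t-test on the Pearson
   correlation between a measure and an outcome: per simulated study, draw
   participants with replacement, attach an outcome correlated with their
   true measure values at the target r, re-estimate the measure from a
   fresh random n-report subsample per participant, and test.  Power is
   the proportion of simulations with a significant *positive*
   correlation, so the null rate is α/2.

## Numerical and procedural choices

- **SD uses the population divisor n** (the variability index is defined
  with divisor n; a sample-divisor variant is available via ``ddof``).
  The relative SD divides by the *population* maximum
  $\sqrt{(M-l)(u-M)}$, which is free of n and therefore comparable across
  subsample sizes; sample-size-dependent maxima exist in the literature
  but would make accuracy curves compare estimates on different scales.
- **PAC threshold d₀.₉** is the 90th percentile (linear interpolation
  between order statistics, switchable via the percentile ``method``) of
  absolute successive changes pooled over persons.  When PAC is estimated
  on subsamples, d₀.₉ is recomputed from the current subsampled dataset by
  default — the estimator a study with only those observations could
  actually form — while the truth uses the full-data threshold.  A
  fixed-threshold mode is available.
- **Undefined values are NaN**, never silently 0: AR(1) of a constant
  series, relative SD of a constant series at a scale bound, and any
  measure on a series shorter than its minimum length.  Persons with an
  undefined value are dropped pairwise from downstream aggregates.
- **Close selection** considers contiguous runs of n reports whose every
  adjacent gap is ≤ 24 h and returns the run with the smallest
  first-to-last span; ties go to the earliest run.  Runs are never
  concatenated across a > 24 h gap.
- **Distant selection** lays an equally spaced grid from the first to the
  last report and picks the order-preserving set of n distinct reports
  minimising the summed absolute time deviation from the grid, by dynamic
  programming with earliest-report tie-breaks (a greedy nearest-report
  mode is available for comparison).
- **Clock-time windows** are half-open — morning [06, 12), afternoon
  [12, 16), evening [16, 20), night [20, 06) wrapping midnight — so the
  four windows partition the day.  Window/day conditions require ≥ 30
  surviving reports per person (configurable).
- **Bias correction for window sampling** is additive: every
  window-restricted estimate is shifted by the population-mean difference
  between full-record estimates and full window-restricted estimates,
  computed on the same eligible persons.  After correction the corrected
  window estimates have exactly zero population-mean bias and unchanged
  person ranks.  The correction can be disabled.
- **Outcome construction in the power engine.** `simulate_outcome` mixes
  the standardised truth vector with Gaussian noise orthogonalised against
  it, `r·ỹ + sqrt(1−r²)·ε̃`; in exact mode the realised sample correlation
  equals r to numerical precision.  Inside the power engine the target
  correlation must hold at the *population* level so each simulated
  study's sample correlation fluctuates: the default regenerates
  population-mode outcomes per simulated dataset, and a pool mode
  pre-generates one exact-mode outcome vector per simulation against the
  full person set and reads it off at the resampled participants.
  Applying the exact construction to the resampled participants themselves
  would pin every sample correlation at r and collapse power to a step
  function, which is why that combination is not offered as a default.
- **Design frontiers** take, per participant count, the smallest grid
  n_obs with power ≥ the threshold, then enforce monotonicity
  conservatively: the requirement at any participant count is at least the
  requirement at every larger count, so Monte-Carlo dips never promote a
  smaller design.
- **Closed-form oracles.** Fisher's z gives
  power ≈ Φ(atanh r · √(N−3) − z₀.₉₇₅).  Its O(1/N) bias is visible at
  N = 80, r = 0.3: the exact fixed-regressor power (noncentral t with
  ncp r√N/√(1−r²)) is 0.793 versus Fisher-z 0.775.  Tests therefore
  compare the engine to Fisher-z at a simulation count whose Monte-Carlo
  SE dominates this approximation gap, and to the exact noncentral-t value
  at a tighter one.

## The synthetic generator

Latent affect for person i at beep k:

    x_k = μ_i + A·cos(2π(h_k − h_peak)/24) + w·1[weekend] + s_k,

with s_k a stationary AR(1) *in beep order* (persistence φ_i, innovation
scale σ_i, stationary SD σ_i/√(1−φ_i²)).  Observed values are clipped to
[0, 100] and rounded to integers, as a slider would report.  Schedules
place 4 beeps/day (default) uniformly at random inside a 09:00–22:00
window under a ≥ 60 min spacing constraint, via the spacing transform
(sorted uniforms in the slack-shortened window plus k·gap), which samples
the constrained schedule space uniformly and cheaply.

AR(1) in beep order was chosen over a continuous-time
Ornstein–Uhlenbeck process because every in-scope measure is order-based;
the generator's ground truth then corresponds exactly to what the
estimators target.  Boundary handling is by clipping (slider semantics);
clipping and rounding bias recovery near the bounds, so recovery tests use
mid-scale parameters.

Defaults — 200 persons, 28 days × 4 beeps (≈ 112 reports, near the
originating study's average of ~112 reports per person), trait mean 60,
trait SD 12, lognormal innovation scale with median 9, persistence
0.35 ± 0.15, diurnal amplitude 6 peaking at 19:00, weekend shift +3 — are
**placeholders chosen to be plausible for momentary happiness data**; the
person-level distributions of real panels are not public.  Two named
regimes are used in validation:

- a *structureless* regime (φ = 0, no diurnal/weekend terms, common
  innovation SD) where the mean-measure RMSE has the closed form
  σ·√(1/n − 1/N) ≈ σ/√n, used to check the accuracy engine against
  theory (60-day records keep the finite-record correction ≤ 7% at
  n ≤ 30);
- a *strong-structure* regime (diurnal amplitude 12, persistence
  0.7 ± 0.1, weekend shift 4) in which short runs of consecutive reports
  are both strongly autocorrelated and unbalanced over slow structure;
  this is the stipulated condition for the directional prediction that
  close sampling is less accurate than random and distant sampling for
  mean, SD and relative SD.  Under the moderate default regime that
  ordering holds for the mean but is within noise for SD — weak
  beep-to-beep persistence barely penalises consecutive sampling of
  variance — so the directional claims are asserted (and should be
  expected in real data) only where slow structure is substantial.

What passing tests show — and do not show.  The generator has no
missingness or compliance process, no multi-item questionnaires, no
mood-episode (multi-day) dynamics beyond the weekend term, and no
measurement reactivity.  Passing accuracy and power checks on this data
validates the *engines* (estimators, selection algorithms, calibration
against closed forms), not the transferability of any specific RMSE or
power number to a particular real population; the study-design numbers a
user should rely on are the ones computed from their own (or a closely
matched) dataset.

## Problem sizes

Desk-scale validation runs use 200 synthetic persons × 240 reports, 200
subsampling replicates per person, 500–4000 power simulations per cell and
2000 bootstrap resamples; these sizes put Monte-Carlo error well inside
every asserted tolerance while keeping the full suite and the acceptance
script in the minutes range on one CPU.  Production-scale analyses
(thousands of persons, 1000 replicates, 2500 simulations per cell on a
10 × 10 grid) use the same code paths with the defaults.
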