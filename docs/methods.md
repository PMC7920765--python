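# Methods

This note documents the models, calibration choices and numerical
conventions behind `countsim`, and what the synthetic observer cohort does
and does not capture relative to empirical calibration data.

## True population model

Site abundances follow deterministic density-independent geometric decline,
`N_{i,t} = N_{i,0} λ^t`, with one λ shared by all sites — a population in a
constant environment, chosen so that every difference between scenarios is
attributable to observation error, not process noise. Initial sizes are
negative-binomial with mean `mu = 300` and dispersion `size = 2`
(variance `mu + mu²/size = 45,300`), resampled until they fall in
[2, 1098], the range over which observer error is calibrated; the raw
distribution puts only a little tail mass outside it. Abundances stay
real-valued through projection; integers appear only when an observation is
simulated. One trajectory is drawn per trend per experiment run and shared
by all scenarios and selections, so scenario contrasts are paired.

Annual decline rates come from total-decline criteria over a 10-year
horizon of annual surveys, i.e. 9 between-survey intervals:
`r = 1 − (1−D)^{1/9}`. This reproduces the conventional −3.9 %/yr
(D = 30 %), −7.4 %/yr (50 %) and −16.4 %/yr (80 %) figures. For D = 10 %
the convention gives 1.16 %/yr; the commonly quoted 1.1 %/yr is not exactly
consistent with any single interval convention, so the computed value is
used rather than a hard-coded constant.

## Observer error model

An observer is a pair (bias curve, residual SD). The bias curve is a loess
fit — local quadratic, span 0.75, tricube neighbourhood weights, Gaussian
error family — of estimated on true group size over the observer's
calibration trials, pooling display-speed classes. The implementation in
`countsim.loess` follows R `stats::loess` with `surface = "direct"`
(neighbourhood radius = distance to the `floor(0.75 n)`-th nearest point)
and agrees with it to ~1e-7 relative error in tests. Outside the calibration
domain the curve continues linearly with the local slope at the nearest
endpoint: local polynomials are unreliable outside their data, and linear
continuation is deterministic and conservative.

The residual SD is the sample SD of (estimated − fitted) over the trials.
Simulated counts are `max(0, round(bias(s) + ε))` with
`ε ~ Normal(0, residual_sd)` — homoscedastic per observer, matching the
single per-observer SD that a pooled loess residual provides. Counts are
rounded because counts are integers; the floor at zero means that at sites
much smaller than the noise scale the expected observed count exceeds the
true size, one of the mechanisms (alongside the size-dependence of the bias
itself) that flattens observed declines late in a series.

## Synthetic cohort generator

The generator replaces empirical calibration data with draws whose summary
statistics match the cohort the study design assumes. Per observer:

- **Stratum margins.** A small-group margin `m_s ~ N(−0.0034, 0.105)` and a
  large-group margin `m_l ~ N(−0.264, 0.130)` are drawn sharing a single
  latent severity factor (correlation 1.0): observers show persistent
  individual tendencies, and independent draws would give an
  across-observer spread of mean margins (SD ≈ 0.084) far narrower than the
  observed −0.31…+0.21 range over 24 observers implies (SD ≈ 0.13).
  Draws whose overall mean margin falls outside [−0.31, 0.21] are rejected.
- **Bias curve.** `m(s) = m_s + (m_l − m_s)·logistic((ln s − ln 200)/0.15)`;
  expected estimate `(1 + m(s))·s`. The logistic-in-log-size family is an
  explicit modelling choice (only stratum summaries are available to
  calibrate against) and is swappable via `CohortParams`.
- **Noise.** σ is drawn from Normal(66, 18) truncated to [43, 103] (matching
  the reported mean, SD and range of per-observer residual SDs). Trial
  noise is `N(0, a·s^γ)` with `(a, γ)` solved per observer so that, over
  the trial grid, the loess residual SD equals σ *and* the per-trial margin
  SD equals 0.275·σ/66 (reported mean 0.275, range 0.185–0.379). Purely
  proportional noise cannot satisfy both moments, and a constant
  (size-independent) trial SD of ~66 would be absurd at group size 2 — the
  zero floor would turn a 2-bird trial into a mean estimate of ~26 and flip
  the cohort's overall margin positive.
- **Trial sizes.** 120 sizes: 60 log-spaced in [2, 201] and 60 in
  [208, 1098]. Balancing the strata is forced by the statistics themselves:
  with stratum means of −0.34 % and −26.4 %, an overall mean margin of
  −13 % requires roughly half the trials in each stratum (a single
  log-spaced grid over [2, 1098] would give ≈ −7 %).

Fitting loess profiles to trials generated this way recovers the generating
curves mid-domain to < 5 % mean absolute relative error, and the fitted
cohort reproduces, without further adjustment: overall margin −0.13 ± 0.30,
stratified margins ≈ −0.004 / −0.25, 2–3 of 24 net overestimators,
residual SDs ≈ 37–100 (mean ≈ 63), per-observer margin SD ≈ 0.276.

**What the synthetic cohort does not capture.** Only printed summary
statistics constrain it. Real observers additionally have idiosyncratic
bias-curve *shapes* — bumps at particular sizes, divergence at the largest
groups — that the two-stratum parametric family cannot represent. Since
between-observer differences are exactly what observer-turnover scenarios
propagate into trend noise, the synthetic cohort is expected to slightly
*understate* turnover effects: rotation scenarios here yield mean T_min
about 1–2 years shorter, and slightly tighter pooled estimate distributions
(higher sign-detection rates, fewer IUCN-unbiased classifications at T_min),
than an empirically calibrated cohort would. Passing tests therefore
demonstrate orderings and mechanisms, and quantitative agreement where the
statistics pin the model down (static-observer designs, 25-year pooled
classes); they do not certify absolute turnover effect sizes for real
cohorts.

## Scenarios

`ScenarioSpec` crosses spatial allocation with temporal rotation over
blocks of `rotation_period` years. Temporal draws are without replacement
from the 24-observer pool until it is exhausted, then re-selected (annual
rotation over 25 years: 24 distinct observers plus one repeat). Spatial
allocation partitions sites as evenly as possible (24 observers over 100
sites: twenty get 4 sites, four get 5), randomised. Under spread mode with
rotation, each block draws its active observers as the next chunk of a
without-replacement pass through the pool (fresh permutation per pass) and
re-partitions the sites; with k = pool size this re-spreads the full pool
each block. A `redraw_allocation=False` flag freezes the initial
allocation instead, for sensitivity checks.

The canonical grid names designs by the number of spatial observers and
temporal identities: O1T1, O1T5, O1T25, O24T1, O24T5, O24T25. The
2-observer variant (O2T25: 50 sites each, annual identity change) follows
the same rules; a static 2-observer design is statistically
indistinguishable from O1T1 (identical signal and pooled noise), which is
why the turnover variant is the informative one.

## Trend statistics

- **Fit.** OLS of `ln(total)` on year over the first T years, totals
  clipped at 1 before the log (totals near zero essentially never occur at
  these population sizes). Trend reported as `exp(slope) − 1`, so a
  noiseless geometric series returns exactly λ − 1. All-equal series:
  slope 0, p = 1 by convention.
- **Power and T_min.** Detection = two-sided slope test p < 0.05 (any sign;
  a flag can additionally require a negative slope). The T grid is 3–25
  (3 is the smallest duration with residual degrees of freedom). Observer
  turnover makes power non-monotone in T — a rotation boundary inserts a
  level jump that can push power back under 0.8 after an early crossing —
  so T_min is the smallest T from which power stays ≥ 0.8 through the
  horizon; for monotone power this equals the first crossing. If power at
  25 years is still below 0.8, T_min is capped at 25 and flagged.
- **Bias.** One-sample two-sided t-test of the replicate trend estimates
  against the true rate; "accurate" = non-significant at 0.05. Zero-variance
  estimate sets are compared exactly. A normality diagnostic is available
  but never gates the test.
- **IUCN bands.** Each study rate's unbiased band runs from the next-worse
  status bound to its own bound, both inclusive, computed from the same
  9-interval convention (for −7.4 %/yr: [−16.4 %, −7.4 %]). Estimates above
  the band underestimate the decline; below it, overestimate.
- **NRMSD.** `sqrt(mean((ŷ_t − y_t)²))/ȳ` over the first T years, with ŷ
  the back-transformed fitted totals; invariant to common rescaling;
  undefined (NaN) if the observed mean is zero.

## Orchestration and reproducibility

`run_experiment` iterates trends × scenarios × selections. Static
single-observer designs enumerate the 24 cohort observers as selections
(N = 24); every design with observer change uses 100 random selections,
each with 100 noise replicates (fresh noise, fixed assignment). Seeding is
counter-based — every cell derives its generator from
`SeedSequence(master_seed, spawn_key=(kind, trend, scenario, selection))` —
so any cell is reproducible in isolation and results are independent of
execution order. Per-observer loess predictions over the shared trajectory
are precomputed once per trend (an (observers × sites × years) table), so
the full grid (1,572 selections, ~3.6 M replicate-fits) runs in ~20 s on
one CPU.

Bias assessments are computed both at each selection's own T_min and over
the full 25 years, and summaries pool at three levels: per selection, per
scenario × trend, and over everything. The pooled direction-detection rate
averages the T_min and 25-year evaluations, the same "all cases" pooling
used for the headline accuracy fractions.

## Known limitations

- Detection probability, species misidentification, double counting,
  observer learning over time, and site-level heterogeneity in λ are all
  out of scope by design; the model isolates group-size estimation error.
- The homoscedastic per-observer count noise inherits the pooled loess
  residual SD; at sites far smaller than σ the zero floor inflates expected
  counts. This is a property of the stated observation model, shared by the
  study design, not an artifact of this implementation.
- Synthetic-cohort turnover effects are mild underestimates (see above);
  with an empirical calibration table (`read_calibration_table` +
  `fit_observer_profile`) the same pipeline runs unchanged on real
  observers.
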