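# countsim

Simulation study of how **observer group-size estimation error** and
**observer turnover** degrade the detection and estimation of wildlife
population trends.

Counts of highly gregarious animals (waterbird flocks, seabird colonies,
cetacean groups) are visual estimates of group size, not censuses. Observers
systematically underestimate large groups, differ widely from one another,
and change over the lifetime of a monitoring scheme — across years, and
across the sites of a survey network. `countsim` asks what that does to the
two quantities managers actually use:

- **T_min** — the minimum number of monitoring years before a log-linear
  trend test reaches statistical power ≥ 0.8 (α = 0.05, capped at 25 years);
- the **accuracy of the trend estimate** — bias t-tests against the true
  rate, classification against IUCN Red List status bands, and the NRMSD
  precision of the fit.

It is written for quantitative ecologists designing or auditing count-based
monitoring programmes.

## Model

**True population.** A population on `S = 100` sites declines
deterministically and density-independently, `N_{t+1} = N_t λ`, identical λ
at every site over 25 years. Initial site sizes are negative-binomial
(`mu = 300`, `size = 2`), kept within the 2–1,098 range on which the
observer error model is calibrated. Annual rates derive from IUCN criterion-A
style declines over a 10-survey horizon (9 intervals),
`r = 1 − (1 − D)^{1/9}`: D = 10 % → −1.2 %/yr (Declining), 30 % → −3.9 %/yr
(Vulnerable), 50 % → −7.4 %/yr (Endangered), 80 % → −16.4 %/yr (Critically
Endangered).

**Observers.** Each observer's error model is a loess bias curve — a local
quadratic regression (span 0.75, tricube weights, Gaussian family; verified
against R's `stats::loess`) of estimated on true group size fitted to 120
calibration trials — plus additive Gaussian count noise with the SD of the
loess residuals. An observed count is
`max(0, round(bias(s) + ε))`, `ε ~ N(0, σ_obs)`.

A synthetic cohort generator (`countsim.synthetic_observers`) emulates the
calibration cohort the study design assumes, so the whole pipeline runs
without any external data: 24 observers, overall mean margin of error −13 %
(SD 28 %), near-zero bias for groups of 2–201 but −26 % for groups of
208–1,098, per-observer mean margins spanning roughly −0.31 to +0.21 with
~2 of 24 net overestimators, per-observer margin SD ≈ 0.275, and residual
SDs in 43–103 individuals (mean ≈ 66).

**Scenarios.** Who counts what and when: spatial allocation (one observer
covers all sites, or k observers partition them as evenly as possible)
crossed with temporal rotation (identities fixed, changing every 5 years, or
annually; without-replacement draws from the pool, re-selection once the
pool is exhausted). Canonical names `O1T1 … O24T25`, plus generalisations
such as `O2T25` (2 observers, 50 sites each, annual turnover).

**Statistics.** Observed yearly totals (sums of simulated counts over sites)
are fitted by OLS of `ln(total)` on year for every duration T = 3…25; power
at T is the fraction of 100 noise replicates with a significant slope, and
T_min is the smallest duration from which power stays ≥ 0.8. Accuracy is
assessed by one-sample t-tests of replicate trend estimates
(`exp(slope) − 1`) against the true rate, by IUCN band classification
(an estimate is *unbiased* if it implies the same Red List status), and by
NRMSD = RMSD(fitted, observed)/mean(observed).

## Worked example

```python
from countsim import ExperimentConfig, run_experiment, summarize

cfg = ExperimentConfig(trends=("endangered",),
                       scenarios=("O1T1", "O1T5", "O1T25"),
                       n_selections=100, n_replicates=100, seed=1)
result = run_experiment(cfg)
print(summarize(result)["tmin"].round(2))
```

```
  scenario       trend  mean    sd    n
0     O1T1  endangered  4.62  0.49   24
1     O1T5  endangered  6.16  2.68  100
2    O1T25  endangered  8.32  1.43  100
```

Reading: at a true decline of −7.4 %/yr, a single unchanging observer
detects the trend after ~5 years; if the observer changes every 5 years
detection needs ~6 years (with far higher variability across rotations,
SD 2.7); annual observer changes push it past 8 years. The per-selection
table (`result.selections`) also carries, for each observer selection, the
replicate-mean trend estimate at T_min and at 25 years, its bias t-test,
IUCN band class and NRMSD.

The numbered drivers under `analysis/` run the full study pipeline —
cohort generation and calibration summaries, the IUCN rate table, the
3-trend × 6-scenario grid, and observer-number variants — writing summary
tables to `results/`. The command line mirrors them
(`countsim generate-cohort | fit-cohort | run | summarize`).

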