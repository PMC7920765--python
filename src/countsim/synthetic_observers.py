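"""Synthetic observer cohorts emulating the calibration experiment.

Real calibration data come from 24 experienced observers who each estimated
120 displayed groups of 2-1,098 individuals. This module generates cohorts
with the same statistical signature so every downstream stage can run and
be tested without the empirical table: per-observer relative bias that is
near zero for small groups (mean -0.34%, SD 10.5% across observers) and
strongly negative for large groups (mean -26.4%, SD 13.0%), an overall
cohort mean margin near -13%, roughly 2 in 24 observers overestimating on
average, and additive count noise with SD in [43, 103] individuals
(mean ~66).

The generating bias model is m(s) = m_small + (m_large - m_small) *
logistic((ln s - ln 200) / w): a smooth logistic transition in log size
between a per-observer small-group margin and large-group margin, centred
near the ~200-individual boundary the stratified summaries use. Estimated
counts are round((1 + m(s)) * s + eps), eps ~ Normal(0, sigma_obs),
floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .observer_model import (
    CalibrationTrial,
    ObserverProfile,
    fit_observer_profile,
    write_calibration_csv,
)

__all__ = ["CohortParams", "Cohort", "default_trial_sizes", "generate_observer", "generate_cohort"]


def default_trial_sizes(n_small: int = 60, n_large: int = 60) -> np.ndarray:
    """Default trial group-size grid: log-spaced within each size stratum.

    Half the trials cover small groups (2-201) and half large groups
    (208-1098), balancing the strata so that with stratum margins of
    -0.34% and -26.4% the cohort's overall mean margin lands near the
    observed -13%.
    """
    small = np.rint(np.geomspace(2, 201, n_small))
    large = np.rint(np.geomspace(208, 1098, n_large))
    return np.concatenate([small, large]).astype(int)


@dataclass
class CohortParams:
    """Targets for a synthetic observer cohort.

    Margins are dimensionless fractions ((estimated - true) / true);
    residual SDs are in individuals. ``small_group_margin`` and
    ``large_group_margin`` are (mean, sd) of the per-observer stratum
    margins across the cohort; ``mean_margin_range`` bounds each observer's
    overall mean margin (draws outside are rejected and redrawn).
    """

    n_observers: int = 24
    mean_margin_range: tuple[float, float] = (-0.31, 0.21)
    overall_mean_margin: float = -0.13
    small_group_margin: tuple[float, float] = (-0.0034, 0.105)
    large_group_margin: tuple[float, float] = (-0.264, 0.130)
    residual_sd_range: tuple[float, float] = (43.0, 103.0)
    residual_sd_mean: float = 66.0
    residual_sd_sd: float = 18.0
    margin_sd_mean: float = 0.275
    stratum_margin_correlation: float = 1.0
    transition_size: float = 200.0
    transition_width: float = 0.15
    trial_sizes: np.ndarray = field(default_factory=default_trial_sizes)
    seed: int | None = None

    def __post_init__(self):
        if self.n_observers < 0:
            raise ValueError("n_observers must be >= 0")
        if self.mean_margin_range[0] > self.mean_margin_range[1]:
            raise ValueError("mean_margin_range must be ordered")
        if self.residual_sd_range[0] > self.residual_sd_range[1]:
            raise ValueError("residual_sd_range must be ordered")
        for name in ("small_group_margin", "large_group_margin"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        self.trial_sizes = np.asarray(self.trial_sizes, dtype=int)
        if self.trial_sizes.size and self.trial_sizes.min() < 1:
            raise ValueError("trial sizes must be >= 1")


@dataclass
class Cohort:
    """A generated cohort: fitted profiles plus generating ground truth."""

    profiles: list[ObserverProfile]
    trials: list[list[CalibrationTrial]]
    bias_functions: list[Callable[[np.ndarray], np.ndarray]]
    noise_sds: list[float]
    params: CohortParams

    def __len__(self) -> int:
        return len(self.profiles)

    def all_trials(self) -> list[CalibrationTrial]:
        return [t for obs in self.trials for t in obs]

    def write_csv(self, path) -> None:
        write_calibration_csv(self.all_trials(), path)


def _bias_function(m_small, m_large, center, width) -> Callable:
    def bias(s):
        s = np.asarray(s, dtype=float)
        z = (np.log(s) - np.log(center)) / width
        m = m_small + (m_large - m_small) / (1.0 + np.exp(-z))
        return (1.0 + m) * s

    return bias


def _trial_noise_sd(
    params: CohortParams,
    sizes: np.ndarray,
    sigma: float,
    m_small: float,
    m_large: float,
) -> np.ndarray:
    """Per-trial noise SD: a power law a * s**gamma in group size.

    An observer's error in individuals grows with group size, but less than
    proportionally (small groups are counted almost exactly in relative
    terms worse than large ones are in absolute terms). The exponent gamma
    and scale a are set so that over the trial grid the noise reproduces
    two calibration statistics at once: the absolute loess-residual SD
    (``sigma``, the quantity the downstream count simulation reuses) and
    the per-observer SD of the trial margins of error
    (``margin_sd_mean`` at the reference residual SD, scaled
    proportionally with sigma). Purely proportional noise (gamma = 1)
    cannot satisfy both.
    """
    s = sizes.astype(float)
    if sigma == 0.0 or s.size == 0:
        return np.zeros_like(s)
    target_margin_sd = params.margin_sd_mean * sigma / params.residual_sd_mean
    # variance of the margin already explained by the bias curve's size trend
    m_curve = _bias_function(m_small, m_large, params.transition_size,
                             params.transition_width)(s) / s - 1.0
    noise_margin_var = target_margin_sd**2 - float(np.var(m_curve))
    ratio = sigma**2 / max(noise_margin_var, 1e-6)

    def moment_ratio(gamma):
        return float(np.mean(s ** (2 * gamma)) / np.mean(s ** (2 * gamma - 2)))

    lo_g, hi_g = 0.0, 1.5
    if ratio >= moment_ratio(hi_g):
        gamma = hi_g
    elif ratio <= moment_ratio(lo_g):
        gamma = lo_g
    else:
        from scipy.optimize import brentq

        gamma = brentq(lambda g: moment_ratio(g) - ratio, lo_g, hi_g, xtol=1e-6)
    a = sigma / float(np.sqrt(np.mean(s ** (2 * gamma))))
    return a * s**gamma


def _draw_margins(params: CohortParams, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one observer's (small, large) stratum margins.

    The two margins share a latent observer-severity factor with
    correlation ``stratum_margin_correlation`` (default 1: an observer who
    underestimates badly does so for small and large groups alike — the
    persistent individual tendency the calibration experiment showed, and
    the choice whose implied across-observer spread of mean margins best
    matches the observed [-0.31, +0.21] range over 24 observers).
    """
    lo, hi = params.mean_margin_range
    rho = params.stratum_margin_correlation
    if not -1.0 <= rho <= 1.0:
        raise ValueError("stratum_margin_correlation must be in [-1, 1]")
    for _ in range(1000):
        u = rng.standard_normal()
        v = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
        m_s = params.small_group_margin[0] + params.small_group_margin[1] * u
        m_l = params.large_group_margin[0] + params.large_group_margin[1] * v
        if lo <= 0.5 * (m_s + m_l) <= hi:
            return m_s, m_l
    raise RuntimeError("could not draw observer margins inside mean_margin_range")


def generate_observer(
    params: CohortParams,
    rng: np.random.Generator,
    observer_id: str = "synthetic-obs",
):
    """Generate one observer's calibration trials and ground-truth bias.

    Returns ``(trials, bias_fn, noise_sd)``: the simulated trials at
    ``params.trial_sizes``, the generating expected-estimate function
    s -> E[estimate], and the generating noise SD.
    """
    m_small, m_large = _draw_margins(params, rng)
    lo, hi = params.residual_sd_range
    mu, sd = params.residual_sd_mean, params.residual_sd_sd
    if sd > 0 and hi > lo:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        sigma = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    else:
        sigma = float(np.clip(mu, lo, hi))
    bias_fn = _bias_function(m_small, m_large, params.transition_size, params.transition_width)
    sizes = params.trial_sizes
    noise_sd = _trial_noise_sd(params, sizes, sigma, m_small, m_large)
    eps = rng.normal(0.0, noise_sd)
    est = np.maximum(np.rint(bias_fn(sizes) + eps), 0).astype(int)
    trials = [
        CalibrationTrial(observer_id=observer_id, true_size=int(s), estimated_size=int(e))
        for s, e in zip(sizes, est)
    ]
    return trials, bias_fn, sigma


def generate_cohort(params: CohortParams, rng: np.random.Generator | None = None) -> Cohort:
    """Generate a cohort of ``params.n_observers`` fitted observer profiles.

    Reproducible: a fixed ``params.seed`` (or an explicitly passed ``rng``
    state) yields an identical cohort.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    profiles, all_trials, fns, sds = [], [], [], []
    for i in range(params.n_observers):
        oid = f"obs{i + 1:02d}"
        trials, fn, sigma = generate_observer(params, rng, observer_id=oid)
        profiles.append(fit_observer_profile(trials))
        all_trials.append(trials)
        fns.append(fn)
        sds.append(sigma)
    return Cohort(profiles=profiles, trials=all_trials, bias_functions=fns,
                  noise_sds=sds, params=params)
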