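"""Experiment orchestration: the full trends x scenarios x selections x
replicates grid, with counter-based seeding, result tables and summaries.

One run simulates, for each true trend, a 100-site declining population
over 25 years; for each observer-change scenario and each random selection
of observers it draws an assignment table, simulates replicate observed
series (fresh count noise per replicate, fixed assignment), fits
log-linear trends over all monitoring durations, and derives T_min, bias
t-tests (at T_min and at 25 years), IUCN-band classifications, direction
detection and NRMSD curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .observer_model import ObserverProfile
from .population_sim import (
    IUCN_DECLINE_CRITERIA,
    init_site_sizes,
    iucn_annual_rate,
    project_trajectory,
)
from .scenarios import CANONICAL_SCENARIOS, ScenarioSpec, build_assignment
from .synthetic_observers import Cohort, CohortParams, generate_cohort
from .trend_stats import (
    DEFAULT_T_GRID,
    bias_ttest,
    classify_iucn,
    iucn_band,
    loglinear_grid,
    sustained_tmin,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "summarize",
           "simulate_replicate_totals", "observer_expectation_cache"]

#: The paper-style study trends: IUCN statuses whose 10-year decline
#: criteria set the annual rates.
DEFAULT_TRENDS = ("declining", "vulnerable", "endangered")


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run.

    ``trends`` are IUCN status names (see ``IUCN_DECLINE_CRITERIA``) or
    explicit annual rates as floats (negative for declines).
    ``scenarios`` are canonical names ("O1T5") or :class:`ScenarioSpec`s.
    For scenarios without observer change (single observer, no rotation)
    each cohort observer serves as one selection, so the effective number
    of selections is the cohort size; all other scenarios use
    ``n_selections`` random observer draws.
    """

    trends: Sequence = DEFAULT_TRENDS
    scenarios: Sequence = CANONICAL_SCENARIOS
    n_selections: int = 100
    n_replicates: int = 100
    n_sites: int = 100
    n_years: int = 25
    nb_mean: float = 300.0
    nb_size: float = 2.0
    cohort_params: CohortParams = field(default_factory=CohortParams)
    calibration_csv: str | None = None
    seed: int = 0

    def resolved_trends(self) -> list[tuple[str, float]]:
        """(label, annual rate) pairs; rates are negative fractions/year."""
        out = []
        for t in self.trends:
            if isinstance(t, str):
                out.append((t, -iucn_annual_rate(IUCN_DECLINE_CRITERIA[t])))
            else:
                out.append((f"rate{float(t):+.4f}", float(t)))
        return out

    def resolved_scenarios(self) -> list[ScenarioSpec]:
        return [
            s if isinstance(s, ScenarioSpec)
            else ScenarioSpec.from_name(s, n_sites=self.n_sites, n_years=self.n_years)
            for s in self.scenarios
        ]


@dataclass
class ExperimentResult:
    """Result bundle: per-selection table, long power/NRMSD tables, manifest."""

    selections: pd.DataFrame
    power: pd.DataFrame
    nrmsd: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.selections.to_csv(outdir / "selections.csv", index=False)
        self.power.to_csv(outdir / "power_by_T.csv", index=False)
        self.nrmsd.to_csv(outdir / "nrmsd_by_T.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


# ---------------------------------------------------------------------------
# simulation kernels
# ---------------------------------------------------------------------------


def observer_expectation_cache(
    profiles: Sequence[ObserverProfile], site_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expected observed size for every observer at every (site, year) cell.

    Returns (mu, sd): mu has shape (n_observers, n_sites, n_years); sd is
    the per-observer residual SD vector. Evaluating each bias curve once
    over the shared true trajectory lets any assignment table be simulated
    by indexing.
    """
    n_obs = len(profiles)
    mu = np.empty((n_obs,) + site_sizes.shape)
    for i, prof in enumerate(profiles):
        mu[i] = prof.bias_curve(site_sizes.ravel()).reshape(site_sizes.shape)
    sd = np.array([p.residual_sd for p in profiles])
    return mu, sd


def simulate_replicate_totals(
    mu_cache: np.ndarray,
    sd: np.ndarray,
    assignment: np.ndarray,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed yearly totals for replicate noise draws under one assignment.

    ``assignment[site, year]`` indexes observers in ``mu_cache``/``sd``.
    Each replicate adds fresh Gaussian count noise per cell, rounds to
    integer counts floored at zero, and sums over sites. Returns an
    (n_replicates, n_years) array.
    """
    cell_mu = np.take_along_axis(mu_cache, assignment[None, :, :], axis=0)[0]
    cell_sd = sd[assignment]
    eps = rng.standard_normal((n_replicates,) + assignment.shape) * cell_sd
    obs = np.maximum(np.rint(cell_mu + eps), 0.0)
    return obs.sum(axis=1)


def _nrmsd_curve(totals: np.ndarray, fits: dict, T_grid) -> np.ndarray:
    """Replicate-mean NRMSD at each monitoring duration."""
    out = np.empty(len(T_grid))
    for j, T in enumerate(T_grid):
        t = np.arange(T)
        yhat = np.exp(fits["intercept"][:, j, None] + fits["slope"][:, j, None] * t)
        y = totals[:, :T]
        rmsd = np.sqrt(np.mean((yhat - y) ** 2, axis=1))
        out[j] = float(np.mean(rmsd / y.mean(axis=1)))
    return out


def _selection_pools(scenario: ScenarioSpec, n_cohort: int, n_selections: int):
    """Observer pools per selection.

    Designs without any observer change (k = 1, no rotation) enumerate the
    cohort: selection i is observer i alone. All other designs draw from
    the full cohort, with ``n_selections`` random selections.
    """
    static = scenario.n_spatial_observers == 1 and scenario.rotation_period >= scenario.n_years
    if static:
        return [[i] for i in range(n_cohort)]
    return [list(range(n_cohort))] * n_selections


def run_experiment(config: ExperimentConfig, cohort: Cohort | None = None) -> ExperimentResult:
    """Run the full grid and collect per-selection results.

    Seeding is counter-based: every (trend, scenario, selection) cell draws
    its RNG from ``SeedSequence(config.seed, spawn_key=...)`` so cells are
    reproducible in isolation and independent of execution order.
    """
    if cohort is None:
        params = config.cohort_params
        cohort_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0,))
        )
        cohort = generate_cohort(params, rng=cohort_rng)
    n_cohort = len(cohort)
    if n_cohort == 0:
        raise ValueError("cohort is empty")

    T_grid = DEFAULT_T_GRID
    t25 = int(T_grid[-1])
    trends = config.resolved_trends()
    scenario_specs = config.resolved_scenarios()

    rows, power_rows, nrmsd_rows = [], [], []
    for ti, (trend_name, true_rate) in enumerate(trends):
        lam = 1.0 + true_rate
        pop_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, ti))
        )
        init = init_site_sizes(config.n_sites, config.nb_mean, config.nb_size, pop_rng)
        traj = project_trajectory(init, lam, config.n_years)
        mu_cache, sd = observer_expectation_cache(cohort.profiles, traj.site_sizes)
        try:
            band = iucn_band(true_rate)
        except ValueError:
            band = None

        for si, spec in enumerate(scenario_specs):
            pools = _selection_pools(spec, n_cohort, config.n_selections)
            for sel, pool in enumerate(pools):
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(2, ti, si, sel))
                )
                assignment = build_assignment(spec, np.asarray(pool), rng)
                totals = simulate_replicate_totals(
                    mu_cache, sd, assignment, config.n_replicates, rng
                )
                fits = loglinear_grid(totals, T_grid)

                power = (fits["p"] < 0.05).mean(axis=0)
                t_min, capped = sustained_tmin(power, T_grid)
                jmin = int(T_grid.index(t_min))
                j25 = len(T_grid) - 1

                row = {
                    "trend": trend_name,
                    "true_rate": true_rate,
                    "scenario": spec.name,
                    "selection": sel,
                    "t_min": t_min,
                    "capped": capped,
                }
                for tag, j, T_eval in (("tmin", jmin, t_min), ("25", j25, t25)):
                    est = fits["trend_rate"][:, j]
                    tstat, p, accurate = bias_ttest(est, true_rate)
                    mean_est = float(est.mean())
                    row[f"mean_trend_{tag}"] = mean_est
                    row[f"ttest_p_{tag}"] = p
                    row[f"accurate_{tag}"] = accurate
                    row[f"iucn_class_{tag}"] = (
                        classify_iucn(mean_est, true_rate, band=band)
                        if band is not None else "undefined"
                    )
                    row[f"direction_frac_{tag}"] = float((np.sign(est) == np.sign(true_rate)).mean())
                nr = _nrmsd_curve(totals, fits, T_grid)
                row["nrmsd_tmin"] = float(nr[jmin])
                row["nrmsd_25"] = float(nr[j25])
                rows.append(row)
                base = {"trend": trend_name, "scenario": spec.name, "selection": sel}
                power_rows.append({**base, **{int(T): float(p) for T, p in zip(T_grid, power)}})
                nrmsd_rows.append({**base, **{int(T): float(v) for T, v in zip(T_grid, nr)}})

    manifest = {
        "seed": config.seed,
        "n_cohort": n_cohort,
        "n_replicates": config.n_replicates,
        "n_selections": config.n_selections,
        "n_sites": config.n_sites,
        "n_years": config.n_years,
        "trends": [
            {"label": name, "annual_rate": rate} for name, rate in trends
        ],
        "scenarios": [s.name for s in scenario_specs],
    }
    return ExperimentResult(
        selections=pd.DataFrame(rows),
        power=pd.DataFrame(power_rows),
        nrmsd=pd.DataFrame(nrmsd_rows),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Aggregate a run at the study's reporting levels.

    Returns tables: ``tmin`` (mean +/- SD T_min per scenario x trend),
    ``pooled`` (accurate / bias-class / direction fractions pooled over
    all trends and scenarios, at T_min and at the full horizon), and
    ``bias_by_cell`` (the same fractions per scenario x trend).
    """
    df = result.selections
    if df.empty:
        raise ValueError("empty result")

    tmin = (
        df.groupby(["scenario", "trend"], sort=False)["t_min"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )

    def _fractions(sub: pd.DataFrame) -> dict:
        out = {"n": len(sub)}
        for tag in ("tmin", "25"):
            out[f"accurate_{tag}"] = float(sub[f"accurate_{tag}"].mean())
            out[f"direction_{tag}"] = float(sub[f"direction_frac_{tag}"].mean())
            cls = sub[f"iucn_class_{tag}"].value_counts(normalize=True)
            for c in ("overestimated", "unbiased", "underestimated"):
                out[f"{c}_{tag}"] = float(cls.get(c, 0.0))
        return out

    pooled = pd.DataFrame([_fractions(df)])
    by_cell = (
        df.groupby(["scenario", "trend"], sort=False)
        .apply(lambda g: pd.Series(_fractions(g)), include_groups=False)
        .reset_index()
    )
    return {"tmin": tmin, "pooled": pooled, "bias_by_cell": by_cell}
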