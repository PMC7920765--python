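"""Per-observer group-size estimation error: calibration data, bias curves,
and simulation of observed counts.

An observer's error model is a loess bias curve (expected estimated size as
a function of true size, fitted to their calibration trials) plus additive
homoscedastic Gaussian noise whose scale is the standard deviation of the
loess residuals.  Simulated counts are the bias-curve prediction plus noise,
rounded to the nearest integer and floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .loess import LoessFit

__all__ = [
    "CalibrationTrial",
    "ObserverProfile",
    "MarginSummary",
    "CalibrationFormatError",
    "read_calibration_table",
    "fit_observer_profile",
    "simulate_observed_size",
    "margin_summary",
    "trials_to_frame",
    "write_calibration_csv",
    "STUDY_SIZE_RANGE",
    "DEFAULT_STRATA",
]

#: Group-size range covered by the study-format calibration experiment.
STUDY_SIZE_RANGE = (2, 1098)

#: Size strata used for stratified margin summaries (small vs large groups).
DEFAULT_STRATA = ((2, 201), (208, 1098))

SPEED_CLASSES = ("average", "maximum")


class CalibrationFormatError(ValueError):
    """Raised when a calibration table is structurally unreadable."""


@dataclass(frozen=True)
class CalibrationTrial:
    """One counting trial: an observer's estimate of one displayed group."""

    observer_id: str
    true_size: int
    estimated_size: int
    speed_class: str | None = None

    def __post_init__(self):
        if self.estimated_size < 0:
            raise ValueError("estimated_size must be >= 0")

    @property
    def margin(self) -> float:
        """Relative margin of error, (estimated - true) / true."""
        return (self.estimated_size - self.true_size) / self.true_size


@dataclass
class ObserverProfile:
    """An observer's generative error model.

    ``bias_curve`` maps true group size to the expected observed size; it is
    the loess fit inside ``domain`` and continues linearly (with the local
    slope at the nearest endpoint) outside it. ``residual_sd`` is the scale
    of the additive Gaussian count noise, in individuals.
    """

    observer_id: str
    residual_sd: float
    domain: tuple[float, float]
    _fit: LoessFit = field(repr=False)
    _edge: tuple[tuple[float, float], tuple[float, float]] = field(repr=False)

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def bias_curve(self, true_size):
        """Expected observed size at ``true_size`` (scalar or array)."""
        s = np.asarray(true_size, dtype=float)
        scalar = s.ndim == 0
        s = np.atleast_1d(s)
        lo, hi = self.domain
        (f_lo, d_lo), (f_hi, d_hi) = self._edge
        out = np.empty_like(s)
        inside = (s >= lo) & (s <= hi)
        if inside.any():
            out[inside] = self._fit.predict(s[inside])
        below = s < lo
        out[below] = f_lo + d_lo * (s[below] - lo)
        above = s > hi
        out[above] = f_hi + d_hi * (s[above] - hi)
        return float(out[0]) if scalar else out


@dataclass
class MarginSummary:
    """Overall, per-stratum and per-observer margin-of-error statistics.

    Margins are dimensionless fractions; SDs are sample standard deviations.
    A stratum with no trials is reported with NaN statistics.
    """

    mean_margin: float
    sd_margin: float
    strata: list[tuple[tuple[float, float], float, float]]
    per_observer: dict[str, float]


# ---------------------------------------------------------------------------
# calibration I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("observer_id", "true_size", "estimated_size")


def read_calibration_table(path, min_trials: int = 10) -> list[CalibrationTrial]:
    """Read a calibration CSV into a list of :class:`CalibrationTrial`.

    The table must have columns ``observer_id``, ``true_size`` and
    ``estimated_size``; ``speed_class`` is optional. Observers contributing
    fewer than ``min_trials`` trials are flagged with a warning (their
    trials are still returned).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty calibration table: {path}", stacklevel=2)
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CalibrationFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"calibration table has no rows: {path}", stacklevel=2)
        return []

    bad_rows = []
    for col in ("true_size", "estimated_size"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows.extend(df.index[coerced.isna()].tolist())
        df[col] = coerced
    if bad_rows:
        raise CalibrationFormatError(
            f"{path}: non-numeric size values at row(s) {sorted(set(bad_rows))}"
        )

    has_speed = "speed_class" in df.columns
    trials = [
        CalibrationTrial(
            observer_id=str(row.observer_id),
            true_size=int(row.true_size),
            estimated_size=int(row.estimated_size),
            speed_class=str(row.speed_class) if has_speed else None,
        )
        for row in df.itertuples()
    ]
    counts = df.groupby("observer_id").size()
    thin = counts[counts < min_trials]
    if len(thin):
        warnings.warn(
            "observer(s) with fewer than "
            f"{min_trials} trials: {sorted(map(str, thin.index))}",
            stacklevel=2,
        )
    return trials


def trials_to_frame(trials: Iterable[CalibrationTrial]) -> pd.DataFrame:
    """Calibration trials as a tidy DataFrame."""
    return pd.DataFrame(
        [
            (t.observer_id, t.true_size, t.estimated_size, t.speed_class)
            for t in trials
        ],
        columns=["observer_id", "true_size", "estimated_size", "speed_class"],
    )


def write_calibration_csv(trials: Iterable[CalibrationTrial], path) -> None:
    """Write trials in the calibration CSV dialect (round-trips with the reader)."""
    trials_to_frame(trials).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitting and simulation
# ---------------------------------------------------------------------------


def fit_observer_profile(
    trials: Sequence[CalibrationTrial],
    span: float = 0.75,
    degree: int = 2,
) -> ObserverProfile:
    """Fit one observer's loess bias curve and residual noise scale.

    All trials must belong to a single observer; speed classes are pooled.
    ``residual_sd`` is the sample SD of (estimated - fitted) over the
    trials. The curve's domain is [min true size, max true size]; beyond it
    the curve continues linearly with the endpoint slope.
    """
    trials = list(trials)
    ids = {t.observer_id for t in trials}
    if len(ids) != 1:
        raise ValueError(f"trials must come from exactly one observer, got {sorted(ids)}")
    n_min = max(10, degree + 2)
    if len(trials) < n_min:
        raise ValueError(f"need at least {n_min} trials, got {len(trials)}")
    x = np.array([t.true_size for t in trials], dtype=float)
    y = np.array([t.estimated_size for t in trials], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("true sizes have zero variance; cannot fit a bias curve")

    fit = LoessFit(x, y, span=span, degree=degree)
    resid = fit.residuals()
    residual_sd = float(np.std(resid, ddof=1))
    lo, hi = float(x.min()), float(x.max())
    edge = (fit.predict_with_slope(lo), fit.predict_with_slope(hi))
    return ObserverProfile(
        observer_id=next(iter(ids)),
        residual_sd=residual_sd,
        domain=(lo, hi),
        _fit=fit,
        _edge=edge,
    )


def simulate_observed_size(profile: ObserverProfile, true_size, rng: np.random.Generator):
    """Draw observed count(s) for ``true_size`` under the observer's model.

    Returns ``max(0, round(bias_curve(s) + eps))`` with
    ``eps ~ Normal(0, residual_sd)``, as a non-negative integer (or array).
    """
    s = np.asarray(true_size, dtype=float)
    scalar = s.ndim == 0
    if np.any(s < 0):
        raise ValueError("true_size must be >= 0")
    mu = profile.bias_curve(s)
    eps = rng.normal(0.0, profile.residual_sd, size=np.shape(s))
    obs = np.maximum(np.rint(np.asarray(mu) + eps), 0.0).astype(np.int64)
    return int(obs) if scalar else obs


def margin_summary(
    trials: Sequence[CalibrationTrial],
    strata_bounds: Sequence[tuple[float, float]] = DEFAULT_STRATA,
) -> MarginSummary:
    """Overall, size-stratified and per-observer margin-of-error statistics.

    The margin of a trial is (estimated - true) / true; strata are inclusive
    [lo, hi] ranges of true size. Empty strata yield NaN entries rather than
    an error.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("margin_summary needs at least one trial")
    df = trials_to_frame(trials)
    m = (df.estimated_size - df.true_size) / df.true_size
    strata = []
    for lo, hi in strata_bounds:
        sel = m[(df.true_size >= lo) & (df.true_size <= hi)]
        if len(sel) == 0:
            strata.append(((lo, hi), float("nan"), float("nan")))
        else:
            sd = float(sel.std(ddof=1)) if len(sel) > 1 else 0.0
            strata.append(((lo, hi), float(sel.mean()), sd))
    per_obs = m.groupby(df.observer_id).mean().to_dict()
    return MarginSummary(
        mean_margin=float(m.mean()),
        sd_margin=float(m.std(ddof=1)) if len(m) > 1 else 0.0,
        strata=strata,
        per_observer={str(k): float(v) for k, v in per_obs.items()},
    )
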