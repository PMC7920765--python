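"""Trend statistics on observed population time series.

Observed yearly totals are analysed by log-linear regression (OLS of
ln(total) on year). From replicate simulated series this module derives
statistical power and the minimum monitoring duration T_min (power >= 0.8
at alpha = 0.05, capped at 25 years), one-sample t-tests of the replicate
trend estimates against the true trend, classification of the mean
estimate against IUCN status bands, trend-direction detection, and the
normalized root-mean-square deviation (NRMSD) precision metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .population_sim import IUCN_DECLINE_CRITERIA, iucn_annual_rate

__all__ = [
    "TrendFit",
    "TminResult",
    "BiasAssessment",
    "fit_log_linear",
    "loglinear_grid",
    "power_and_tmin",
    "bias_ttest",
    "assess_bias",
    "classify_iucn",
    "iucn_band",
    "nrmsd",
    "direction_detected",
    "DEFAULT_T_GRID",
]

#: Monitoring durations evaluated: 3 years (minimum for a slope test with
#: residual df) through the 25-year horizon.
DEFAULT_T_GRID = tuple(range(3, 26))


@dataclass
class TrendFit:
    """Log-linear trend fit over the first T years of a series."""

    slope: float           # per-year rate on the log scale
    intercept: float
    p_value: float         # two-sided t-test of slope != 0
    trend_rate: float      # exp(slope) - 1, fraction per year
    years_used: int
    nrmsd: float

    @property
    def fitted(self) -> np.ndarray:
        """Back-transformed fitted totals over the years used."""
        t = np.arange(self.years_used)
        return np.exp(self.intercept + self.slope * t)


@dataclass
class TminResult:
    """Power as a function of monitoring duration and the derived T_min."""

    power_by_T: dict[int, float]
    t_min: int
    capped: bool


@dataclass
class BiasAssessment:
    """Accuracy of replicate trend estimates against the true trend."""

    mean_estimate: float
    t_statistic: float
    p_value: float
    accurate: bool          # t-test non-significant at alpha
    iucn_class: str         # overestimated / unbiased / underestimated
    direction_correct: bool


# ---------------------------------------------------------------------------
# log-linear regression (closed form, vectorised over replicates)
# ---------------------------------------------------------------------------


def _ols_loglinear(y_log: np.ndarray, T: int):
    """OLS of y_log[:, :T] on t = 0..T-1 for every row.

    Returns (slope, intercept, p_value) arrays. Zero-residual series get
    p = 0 for a nonzero slope and p = 1 for a zero slope.
    """
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    y = y_log[:, :T]
    ybar = y.mean(axis=1)
    slope = (y @ tc) / sxx
    intercept = ybar - slope * t.mean()
    resid = y - (intercept[:, None] + slope[:, None] * t)
    rss = np.einsum("ij,ij->i", resid, resid)
    df = T - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    exact = se == 0.0
    p[exact] = np.where(slope[exact] == 0.0, 1.0, 0.0)
    # all-equal series: slope 0, p 1 by convention (no float residue)
    constant = np.ptp(y, axis=1) == 0.0
    slope[constant] = 0.0
    intercept[constant] = ybar[constant]
    p[constant] = 1.0
    return slope, intercept, p


def fit_log_linear(series, T: int) -> TrendFit:
    """Fit ln(total) ~ year over the first ``T`` years of one series.

    Totals are clipped below at 1 before the log transform. The trend rate
    is reported as exp(slope) - 1 so a noiseless geometric series with
    multiplier lambda returns exactly lambda - 1.
    """
    series = np.asarray(series, dtype=float)
    if T < 3:
        raise ValueError("T must be >= 3 for a slope test with residual df")
    if series.size < T:
        raise ValueError(f"series has {series.size} years, needs {T}")
    y = np.log(np.clip(series[:T], 1.0, None))[None, :]
    slope, intercept, p = _ols_loglinear(y, T)
    fitted = np.exp(intercept[0] + slope[0] * np.arange(T))
    return TrendFit(
        slope=float(slope[0]),
        intercept=float(intercept[0]),
        p_value=float(p[0]),
        trend_rate=float(np.expm1(slope[0])),
        years_used=T,
        nrmsd=nrmsd(series[:T], fitted, T),
    )


def loglinear_grid(totals: np.ndarray, T_grid=DEFAULT_T_GRID):
    """Vectorised log-linear fits of replicate series over a grid of T.

    ``totals`` has shape (n_replicates, n_years). Returns dict of arrays
    keyed ``slope``, ``trend_rate``, ``p`` of shape (n_replicates, len(T_grid)),
    plus ``intercept``.
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    y_log = np.log(np.clip(totals, 1.0, None))
    n = totals.shape[0]
    out = {k: np.empty((n, len(T_grid))) for k in ("slope", "intercept", "p")}
    for j, T in enumerate(T_grid):
        s, a, p = _ols_loglinear(y_log, T)
        out["slope"][:, j] = s
        out["intercept"][:, j] = a
        out["p"][:, j] = p
    out["trend_rate"] = np.expm1(out["slope"])
    return out


# ---------------------------------------------------------------------------
# power / T_min
# ---------------------------------------------------------------------------


def power_and_tmin(
    replicate_series,
    alpha: float = 0.05,
    power_threshold: float = 0.8,
    T_grid=DEFAULT_T_GRID,
    require_negative: bool = False,
) -> TminResult:
    """Detection power by monitoring duration and the minimum duration.

    A replicate counts as a detection at duration T when its fitted slope
    is significantly different from zero (p < alpha); with
    ``require_negative`` the slope must also be negative.

    Observer turnover makes the power curve non-monotone in T: a rotation
    boundary injects a level jump that inflates the residual variance and
    can push power back below threshold after an early crossing. T_min is
    therefore the smallest T from which power stays >= ``power_threshold``
    for every longer duration in the grid (for monotone power this is the
    first crossing); if power at the horizon is still below threshold,
    T_min is capped at the last grid value (flagged ``capped``).
    """
    totals = np.atleast_2d(np.asarray(replicate_series, dtype=float))
    if totals.shape[0] < 2:
        raise ValueError("need at least 2 replicate series")
    fits = loglinear_grid(totals, T_grid)
    detected = fits["p"] < alpha
    if require_negative:
        detected &= fits["slope"] < 0
    power = detected.mean(axis=0)
    power_by_T = {int(T): float(p) for T, p in zip(T_grid, power)}
    t_min, capped = sustained_tmin(power, T_grid, power_threshold)
    return TminResult(power_by_T, t_min, capped)


def sustained_tmin(power: np.ndarray, T_grid=DEFAULT_T_GRID,
                   power_threshold: float = 0.8) -> tuple[int, bool]:
    """Smallest grid duration from which power never drops below threshold."""
    power = np.asarray(power, dtype=float)
    below = power < power_threshold
    if below[-1]:
        return int(T_grid[-1]), True
    last_below = np.nonzero(below)[0]
    j = 0 if last_below.size == 0 else int(last_below[-1]) + 1
    return int(T_grid[j]), False


# ---------------------------------------------------------------------------
# bias and precision
# ---------------------------------------------------------------------------


def bias_ttest(trend_estimates, true_trend: float, alpha: float = 0.05):
    """One-sample two-sided t-test of replicate trend estimates vs truth.

    Returns (t_statistic, p_value, accurate) where ``accurate`` means the
    test is non-significant, i.e. the mean estimate is statistically
    indistinguishable from the true trend. With zero variance among the
    estimates the means are compared exactly.
    """
    est = np.asarray(trend_estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 trend estimates")
    if not np.all(np.isfinite(est)):
        raise ValueError("trend estimates must be finite")
    if np.ptp(est) == 0.0:
        equal = est[0] == true_trend
        return (0.0 if equal else np.inf), (1.0 if equal else 0.0), bool(equal)
    t, p = stats.ttest_1samp(est, popmean=true_trend)
    return float(t), float(p), bool(p >= alpha)


def assess_bias(
    trend_estimates,
    true_trend: float,
    alpha: float = 0.05,
    band: tuple[float, float] | None = None,
) -> BiasAssessment:
    """Full accuracy assessment of replicate trend estimates.

    Combines the one-sample t-test against the true trend, the IUCN-band
    classification of the replicate-mean estimate, and direction detection.
    """
    est = np.asarray(trend_estimates, dtype=float)
    t, p, accurate = bias_ttest(est, true_trend, alpha=alpha)
    mean_est = float(est.mean())
    return BiasAssessment(
        mean_estimate=mean_est,
        t_statistic=t,
        p_value=p,
        accurate=accurate,
        iucn_class=classify_iucn(mean_est, true_trend, band=band),
        direction_correct=direction_detected(mean_est, true_trend),
    )


def iucn_band(true_trend: float) -> tuple[float, float]:
    """Unbiased band [lower, upper] of annual rates for a true decline rate.

    The band runs from the next-worse IUCN status bound to the trend's own
    bound: e.g. for a true rate of -7.4%/yr (endangered) any estimate in
    [-16.4%, -7.4%] implies the same conservation status. Bounds are
    derived from the decline criteria via :func:`iucn_annual_rate` and are
    inclusive.
    """
    statuses = list(IUCN_DECLINE_CRITERIA)
    rates = [-iucn_annual_rate(IUCN_DECLINE_CRITERIA[s]) for s in statuses]
    for i, r in enumerate(rates[:-1]):
        if np.isclose(true_trend, r, atol=2e-3):
            return (rates[i + 1], r)
    raise ValueError(
        f"true_trend {true_trend} is not one of the IUCN study rates "
        f"{[round(r, 4) for r in rates[:-1]]}; pass an explicit band"
    )


def classify_iucn(
    mean_estimate: float,
    true_trend: float,
    band: tuple[float, float] | None = None,
) -> str:
    """Classify a mean trend estimate against the IUCN status band.

    Estimates above the band (less negative: the decline looks milder than
    it is) are ``underestimated``; below it, ``overestimated``; inside it
    (inclusive), ``unbiased``.
    """
    lo, hi = band if band is not None else iucn_band(true_trend)
    if lo > hi:
        raise ValueError("band must be (lower, upper)")
    if mean_estimate > hi:
        return "underestimated"
    if mean_estimate < lo:
        return "overestimated"
    return "unbiased"


def nrmsd(observed, fitted, T: int | None = None) -> float:
    """Normalized root-mean-square deviation between observed and fitted totals.

    sqrt(mean((fitted - observed)^2 over T years)) / mean(observed); lower
    values mean a more precise trend fit. Undefined (NaN) when the observed
    mean is zero.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if T is None:
        T = y.size
    if y.size < T or yhat.size < T:
        raise ValueError(f"both series need at least T={T} values")
    y, yhat = y[:T], yhat[:T]
    ybar = y.mean()
    if ybar == 0.0:
        return float("nan")
    return float(np.sqrt(np.mean((yhat - y) ** 2)) / ybar)


def direction_detected(trend_estimate: float, true_trend: float) -> bool:
    """Whether the estimated trend has the same sign as the true trend."""
    return bool(np.sign(trend_estimate) == np.sign(true_trend))
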