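"""Trend statistics: log-linear fits vs an independent OLS oracle, power and
T_min, bias t-tests, IUCN bands, NRMSD, direction detection."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from countsim.trend_stats import (
    assess_bias,
    bias_ttest,
    classify_iucn,
    direction_detected,
    fit_log_linear,
    iucn_band,
    nrmsd,
    power_and_tmin,
)


class TestFitLogLinear:
    def test_noiseless_geometric_series_exact(self):
        series = 30_000 * 0.926 ** np.arange(10)
        fit = fit_log_linear(series, 10)
        assert fit.slope == pytest.approx(np.log(0.926), rel=1e-12)
        assert fit.trend_rate == pytest.approx(-0.074, abs=1e-9)
        assert fit.p_value < 1e-10
        assert fit.nrmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_on_toy_series(self):
        series = np.array([100.0, 90.0, 85.0, 70.0, 66.0])
        fit = fit_log_linear(series, 5)
        t = np.arange(5.0)
        ols = sm.OLS(np.log(series), sm.add_constant(t)).fit()
        assert fit.slope == pytest.approx(ols.params[1], rel=1e-10)
        assert fit.intercept == pytest.approx(ols.params[0], rel=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalues[1], rel=1e-8)

    def test_constant_series_zero_trend(self):
        fit = fit_log_linear(np.full(10, 50.0), 10)
        assert fit.trend_rate == 0.0
        assert fit.p_value == 1.0

    def test_requires_three_years(self):
        with pytest.raises(ValueError):
            fit_log_linear(np.arange(1, 10.0), 2)

    def test_zero_totals_clipped_before_log(self):
        fit = fit_log_linear(np.array([10.0, 0.0, 5.0, 2.0]), 4)
        assert np.isfinite(fit.slope)


class TestPowerAndTmin:
    def test_noiseless_decline_detected_immediately(self):
        series = 30_000 * 0.926 ** np.arange(25)
        reps = np.tile(series, (10, 1))
        res = power_and_tmin(reps)
        assert all(p == 1.0 for p in res.power_by_T.values())
        assert res.t_min == 3 and not res.capped

    def test_type_one_error_calibrated_under_stable_population(self, rng):
        """With no trend, detection rate ~ alpha and T_min is capped."""
        n_rep = 400
        totals = 30_000 * np.exp(rng.normal(0, 0.03, size=(n_rep, 25)))
        res = power_and_tmin(totals)
        rates = np.array(list(res.power_by_T.values()))
        # each T: binomial(400, 0.05) -> SE ~ 0.011
        assert np.all(rates < 0.05 + 4 * 0.011)
        assert rates.mean() == pytest.approx(0.05, abs=0.02)
        assert res.t_min == 25 and res.capped

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            power_and_tmin(np.ones((1, 25)))

    def test_tmin_is_sustained_crossing(self):
        """A dip after an early crossing delays T_min to the stable crossing."""
        reps = np.zeros((10, 25))  # placeholder; use power path directly
        from countsim.trend_stats import sustained_tmin

        power = np.array([0.9] * 3 + [0.5] + [0.95] * 19)
        t_grid = tuple(range(3, 26))
        t_min, capped = sustained_tmin(power, t_grid)
        assert (t_min, capped) == (7, False)
        t_min, capped = sustained_tmin(np.full(23, 0.99), t_grid)
        assert (t_min, capped) == (3, False)
        t_min, capped = sustained_tmin(np.linspace(0, 0.7, 23), t_grid)
        assert (t_min, capped) == (25, True)


class TestBiasTtest:
    def test_exact_estimates_are_accurate(self):
        t, p, ok = bias_ttest(np.full(10, -0.074), -0.074)
        assert ok and p == 1.0

    def test_zero_variance_wrong_mean_is_inaccurate(self):
        _, p, ok = bias_ttest(np.full(10, -0.06), -0.074)
        assert not ok and p == 0.0

    def test_rejection_rate_matches_alpha_under_null(self, rng):
        """~5% of t-tests reject when estimates centre on the true trend."""
        reps = rng.normal(-0.074, 1e-3, size=(10_000, 100))
        mean = reps.mean(axis=1)
        sd = reps.std(axis=1, ddof=1)
        from scipy import stats as ss

        tstat = (mean + 0.074) / (sd / np.sqrt(100))
        reject = 2 * ss.t.sf(np.abs(tstat), 99) < 0.05
        assert reject.mean() == pytest.approx(0.05, abs=0.01)
        # spot-check one row against the package implementation
        t, p, ok = bias_ttest(reps[0], -0.074)
        t2, p2 = ss.ttest_1samp(reps[0], -0.074)
        assert t == pytest.approx(t2) and p == pytest.approx(p2)

    def test_shifted_estimates_detected(self, rng):
        """Mean shifted ~14 SE from truth: essentially always significant."""
        est = rng.normal(-0.06, 1e-3, 100)
        _, _, ok = bias_ttest(est, -0.074)
        assert not ok


class TestIucnClassification:
    def test_endangered_band_bounds(self):
        lo, hi = iucn_band(-0.0741)
        assert lo == pytest.approx(-0.164, abs=5e-4)
        assert hi == pytest.approx(-0.074, abs=5e-4)

    @pytest.mark.parametrize(
        "estimate,expected",
        [
            (-0.10, "unbiased"),
            (-0.05, "underestimated"),
            (-0.20, "overestimated"),
        ],
    )
    def test_classification_against_endangered_trend(self, estimate, expected):
        assert classify_iucn(estimate, -0.074) == expected

    def test_band_bounds_are_inclusive(self):
        lo, hi = iucn_band(-0.074)
        assert classify_iucn(hi, -0.074) == "unbiased"
        assert classify_iucn(lo, -0.074) == "unbiased"
        assert classify_iucn(hi + 1e-9, -0.074) == "underestimated"
        assert classify_iucn(lo - 1e-9, -0.074) == "overestimated"

    def test_unknown_trend_requires_explicit_band(self):
        with pytest.raises(ValueError):
            classify_iucn(-0.05, -0.5)
        assert classify_iucn(-0.05, -0.5, band=(-0.6, -0.4)) == "underestimated"

    def test_assess_bias_combines_checks(self, rng):
        est = rng.normal(-0.10, 1e-3, 100)
        ba = assess_bias(est, -0.074)
        assert ba.iucn_class == "unbiased"
        assert ba.direction_correct
        assert not ba.accurate  # 26 SE from the true value


class TestNrmsd:
    def test_perfect_fit_zero(self):
        y = np.array([100.0, 90.0, 80.0])
        assert nrmsd(y, y, 3) == 0.0

    def test_hand_computed_toy(self):
        assert nrmsd([100.0, 100.0], [90.0, 110.0], 2) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scale=st.floats(1e-3, 1e4),
        seed=st.integers(0, 1000),
        T=st.integers(3, 25),
    )
    def test_scale_invariance(self, scale, seed, T):
        rng = np.random.default_rng(seed)
        y = rng.uniform(50, 150, T)
        yhat = y + rng.normal(0, 5, T)
        base = nrmsd(y, yhat, T)
        assert nrmsd(scale * y, scale * yhat, T) == pytest.approx(base, rel=1e-9)

    def test_zero_mean_undefined(self):
        assert np.isnan(nrmsd([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], 3))


class TestDirection:
    @pytest.mark.parametrize(
        "est,true,expected",
        [(-0.01, -0.074, True), (0.002, -0.074, False), (0.01, 0.02, True)],
    )
    def test_sign_match(self, est, true, expected):
        assert direction_detected(est, true) is expected
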