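"""Observer error model: calibration I/O, profile fitting, count simulation,
margin summaries."""

import numpy as np
import pytest

from countsim.loess import LoessFit
from countsim.observer_model import (
    CalibrationFormatError,
    CalibrationTrial,
    fit_observer_profile,
    margin_summary,
    read_calibration_table,
    simulate_observed_size,
    write_calibration_csv,
)
from tests.test_loess import brute_force_loess


def _make_trials(true, est, observer="A"):
    return [
        CalibrationTrial(observer_id=observer, true_size=int(t), estimated_size=int(e))
        for t, e in zip(true, est)
    ]


# ---------------------------------------------------------------------------
# reading / writing calibration tables
# ---------------------------------------------------------------------------


def test_read_empty_file_warns_and_returns_nothing(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.warns(UserWarning, match="empty"):
        assert read_calibration_table(path) == []


def test_read_toy_table_round_trip(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "observer_id,true_size,estimated_size,speed_class\n"
        "A,10,9,average\nA,100,80,maximum\nB,10,12,average\n"
    )
    with pytest.warns(UserWarning, match="fewer than"):
        trials = read_calibration_table(path)
    assert len(trials) == 3
    assert {t.observer_id for t in trials} == {"A", "B"}
    assert trials[1].estimated_size == 80
    assert trials[2].speed_class == "average"


def test_write_then_read_preserves_trials(tmp_path):
    trials = _make_trials([10, 50, 200, 900], [9, 48, 150, 700])
    path = tmp_path / "cal.csv"
    write_calibration_csv(trials, path)
    back = read_calibration_table(path, min_trials=1)
    assert [(t.true_size, t.estimated_size) for t in back] == [
        (10, 9), (50, 48), (200, 150), (900, 700)
    ]


def test_missing_column_is_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("observer_id,true_size\nA,10\n")
    with pytest.raises(CalibrationFormatError, match="estimated_size"):
        read_calibration_table(path)


def test_non_numeric_size_reports_row_index(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "observer_id,true_size,estimated_size\nA,10,9\nA,oops,80\n"
    )
    with pytest.raises(CalibrationFormatError, match=r"row\(s\) \[1\]"):
        read_calibration_table(path)


# ---------------------------------------------------------------------------
# profile fitting
# ---------------------------------------------------------------------------


def test_perfect_observer_fits_identity():
    sizes = np.unique(np.geomspace(2, 1098, 120).astype(int))
    prof = fit_observer_profile(_make_trials(sizes, sizes))
    query = np.linspace(2, 1098, 200)
    assert np.max(np.abs(prof.bias_curve(query) - query)) < 1.0
    assert prof.residual_sd < 1.0
    assert prof.domain == (2.0, 1098.0)


def test_biased_observer_recovered_and_matches_brute_force(rng):
    sizes = np.linspace(2, 1098, 120)
    est = np.rint(0.8 * sizes + rng.normal(0, 50, sizes.size))
    est = np.maximum(est, 0)
    prof = fit_observer_profile(_make_trials(sizes.astype(int), est))
    # mid-domain curve close to the generating 0.8*s line
    mid = np.linspace(200, 900, 10)
    np.testing.assert_allclose(prof.bias_curve(mid), 0.8 * mid, rtol=0.08)
    # residual_sd recovers the generating noise scale within MC error
    assert prof.residual_sd == pytest.approx(50, rel=0.25)
    # agreement with an independent brute-force local WLS at query points
    x = np.array([t.true_size for t in _make_trials(sizes.astype(int), est)], float)
    oracle = np.array([brute_force_loess(sizes, est, q) for q in mid])
    np.testing.assert_allclose(prof.bias_curve(mid), oracle, rtol=0.01)


def test_extrapolation_is_linear_beyond_domain():
    sizes = np.linspace(100, 1000, 60)
    prof = fit_observer_profile(_make_trials(sizes.astype(int), sizes.astype(int)))
    hi_val = prof.bias_curve(1000.0)
    step = prof.bias_curve(1200.0) - prof.bias_curve(1100.0)
    assert prof.bias_curve(1100.0) == pytest.approx(hi_val + step, rel=1e-6)


@pytest.mark.parametrize(
    "true,est,err",
    [
        ([10] * 12, [9] * 12, "zero variance"),
        (list(range(2, 7)), list(range(2, 7)), "at least"),
    ],
)
def test_fit_rejects_degenerate_trials(true, est, err):
    with pytest.raises(ValueError, match=err):
        fit_observer_profile(_make_trials(true, est))


def test_fit_rejects_mixed_observers():
    trials = _make_trials(range(10, 30), range(10, 30), observer="A")
    trials += _make_trials(range(10, 30), range(10, 30), observer="B")
    with pytest.raises(ValueError, match="one observer"):
        fit_observer_profile(trials)


# ---------------------------------------------------------------------------
# simulating observed counts
# ---------------------------------------------------------------------------


def _identity_profile(residual_sd=0.0):
    sizes = np.linspace(2, 1098, 60)
    prof = fit_observer_profile(_make_trials(sizes.astype(int), sizes.astype(int)))
    prof.residual_sd = residual_sd
    return prof


def test_noiseless_identity_returns_truth(rng):
    prof = _identity_profile(residual_sd=1e-12)
    assert simulate_observed_size(prof, 300, rng) == 300


def test_simulated_counts_follow_stated_law(rng):
    """Counts are round(bias(s) + eps): mean ~ 0.8*500, SD ~ residual_sd."""
    sizes = np.linspace(2, 1098, 120)
    prof = fit_observer_profile(
        _make_trials(sizes.astype(int), np.rint(0.8 * sizes))
    )
    prof.residual_sd = 50.0
    draws = simulate_observed_size(prof, np.full(100_000, 500.0), rng)
    assert draws.mean() == pytest.approx(400.0, abs=3 * 50 / np.sqrt(1e5) + 1.0)
    assert draws.std() == pytest.approx(50.0, rel=0.05)
    assert draws.min() >= 0


def test_truncation_at_zero(rng):
    prof = _identity_profile(residual_sd=30.0)
    draws = simulate_observed_size(prof, np.zeros(5000), rng)
    assert draws.min() >= 0
    # concentrated near max(0, bias(0)): more than half of draws below one SD
    assert np.mean(draws < 30) > 0.5


def test_refit_then_noiseless_simulation_reproduces_curve(rng):
    """Zero-noise simulation at training sizes returns the fitted curve."""
    sizes = np.linspace(2, 1098, 60)
    est = np.rint(0.9 * sizes)
    prof = fit_observer_profile(_make_trials(sizes.astype(int), est))
    prof.residual_sd = 1e-12
    sim = simulate_observed_size(prof, sizes, rng)
    np.testing.assert_array_equal(sim, np.rint(prof.bias_curve(sizes)))


# ---------------------------------------------------------------------------
# margin summaries
# ---------------------------------------------------------------------------


def test_margins_zero_for_perfect_estimates():
    ms = margin_summary(_make_trials([10, 100, 500], [10, 100, 500]))
    assert ms.mean_margin == 0.0
    assert ms.sd_margin == 0.0


def test_margin_hand_computed_toy():
    ms = margin_summary(_make_trials([100, 100], [90, 110]))
    assert ms.mean_margin == pytest.approx(0.0)
    assert ms.sd_margin == pytest.approx(0.1 * np.sqrt(2), rel=1e-12)


def test_empty_stratum_reported_as_nan_not_error():
    ms = margin_summary(
        _make_trials([10, 20], [9, 18]), strata_bounds=((2, 50), (500, 1000))
    )
    (_, m1, _), (_, m2, _) = ms.strata
    assert np.isfinite(m1)
    assert np.isnan(m2)


def test_margin_recovers_known_constant_bias(rng):
    """Trials with constant relative bias b recover mean margin -> b."""
    b = -0.2
    n = 10_000
    true = rng.integers(50, 1000, n)
    est = np.maximum(np.rint((1 + b) * true + rng.normal(0, 5, n)), 0)
    trials = _make_trials(true, est)
    ms = margin_summary(trials)
    mc_se = ms.sd_margin / np.sqrt(n)
    assert abs(ms.mean_margin - b) < 3 * mc_se + 1e-3
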