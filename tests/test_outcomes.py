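"""TSD reaction norm, TSP means, hatching success, per-clutch predictions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from nestherm.metabolism import DevRateCurve, integrate_development
from nestherm.outcomes import (
    HatchLogistic,
    TSDReactionNorm,
    female_probability,
    hatch_probability,
    predict_all,
    predict_egg,
    trt_limits,
    tsp_mean_temperature,
)


class TestReactionNorm:
    def test_pivotal_temperature_gives_even_sex_ratio(self):
        assert female_probability(30.3) == pytest.approx(0.5, abs=1e-12)

    def test_published_trt_endpoints(self):
        """The flatback norm puts mixed sexes between 29.4 and 31.2 C."""
        assert female_probability(29.4) == pytest.approx(0.05, abs=0.005)
        assert female_probability(31.2) == pytest.approx(0.95, abs=0.005)

    def test_strictly_increasing_with_limits(self):
        t = np.linspace(25, 36, 500)
        p = female_probability(t)
        assert np.all(np.diff(p) > 0)
        assert female_probability(20.0) < 1e-6
        assert female_probability(40.0) > 1 - 1e-6

    def test_zero_shape_rejected(self):
        with pytest.raises(ValueError):
            TSDReactionNorm(30.3, 0.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            female_probability(-1.0)


class TestTRTLimits:
    def test_published_values(self):
        lo, hi = trt_limits()
        assert round(lo, 1) == 29.4
        assert round(hi, 1) == 31.2

    def test_closed_form_agrees_with_numerical_inversion(self):
        norm = TSDReactionNorm()
        lo, hi = trt_limits(norm, level=0.05)
        lo_num = brentq(lambda t: female_probability(t, norm) - 0.05, 25, 35, xtol=1e-12)
        hi_num = brentq(lambda t: female_probability(t, norm) - 0.95, 25, 35, xtol=1e-12)
        assert lo == pytest.approx(lo_num, abs=1e-9)
        assert hi == pytest.approx(hi_num, abs=1e-9)

    def test_step_function_limit(self):
        norm = TSDReactionNorm(30.3, -1e-9)
        lo, hi = trt_limits(norm)
        assert lo == pytest.approx(30.3, abs=1e-6)
        assert hi == pytest.approx(30.3, abs=1e-6)

    @given(level=st.floats(0.01, 0.45))
    @settings(deadline=None, max_examples=40)
    def test_limits_invert_the_norm_at_any_level(self, level):
        lo, hi = trt_limits(TSDReactionNorm(), level=level)
        assert female_probability(lo) == pytest.approx(level, abs=1e-9)
        assert female_probability(hi) == pytest.approx(1 - level, abs=1e-9)


class TestTSPMean:
    def test_constant_series(self, hourly_series):
        s = hourly_series(np.full(24 * 60 + 1, 31.0))
        rate = DevRateCurve(t_opt=31.0, r_max=2.0 / 24, sigma_below=1e6, sigma_above=1e6)
        maturity, _ = integrate_development(s, rate)
        mean, complete = tsp_mean_temperature(s, maturity)
        assert mean == pytest.approx(31.0)
        assert complete

    def test_linear_ramp_selects_middle_third(self, hourly_series):
        n = 24 * 50
        temps = np.linspace(30.0, 32.0, n)
        s = hourly_series(temps)
        rate = DevRateCurve(t_opt=31.0, r_max=100.0 / n, sigma_below=1e6, sigma_above=1e6)
        maturity, _ = integrate_development(s, rate)
        mean, _ = tsp_mean_temperature(s, maturity)
        sel = slice(n // 3, 2 * n // 3)
        assert mean == pytest.approx(temps[sel].mean(), abs=0.01)

    def test_pre_term_death_flags_partial_window(self, hourly_series):
        # development stalls at 50%: series simply ends mid-TSP
        n = 24 * 25
        s = hourly_series(np.full(n, 31.0))
        rate = DevRateCurve(t_opt=31.0, r_max=2.0 / 24, sigma_below=1e6, sigma_above=1e6)
        maturity, _ = integrate_development(s, rate)
        assert maturity.iloc[-1] == pytest.approx(50.0, abs=0.2)
        mean, complete = tsp_mean_temperature(s, maturity)
        assert not complete
        assert mean == pytest.approx(31.0)

    def test_never_entering_tsp_raises(self, hourly_series):
        s = hourly_series(np.full(48, 30.0))
        maturity, _ = integrate_development(s, DevRateCurve())
        with pytest.raises(ValueError, match="thermosensitive"):
            tsp_mean_temperature(s, maturity)


class TestHatchLogistic:
    def test_inflection_gives_half(self):
        assert hatch_probability(32.7) == pytest.approx(0.5)

    def test_strictly_decreasing(self):
        assert hatch_probability(30.0) > hatch_probability(35.0)
        t = np.linspace(28, 38, 200)
        assert np.all(np.diff(hatch_probability(t)) < 0)

    def test_slope_changes_steepness_not_inflection(self):
        steep = HatchLogistic(slope=2.0)
        assert hatch_probability(32.7, steep) == pytest.approx(0.5)
        # steeper transition on both sides
        assert hatch_probability(31.7, steep) > hatch_probability(31.7)
        assert hatch_probability(33.7, steep) < hatch_probability(33.7)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            HatchLogistic(slope=0.0)


class _FakeResult:
    def __init__(self, frames):
        self.egg_temps = frames


class TestPredictAll:
    def _series(self, values):
        idx = pd.date_range("2020-12-01", periods=len(values), freq="h")
        return pd.Series(np.asarray(values, dtype=float), index=idx)

    def test_identical_series_zero_spread(self):
        base = 31.0 + 0.5 * np.sin(np.arange(24 * 60 + 1) * 2 * np.pi / 24)
        frames = pd.DataFrame({e: base for e in range(4)},
                              index=self._series(base).index)
        table, summary = predict_all(_FakeResult(frames))
        assert table["duration_days"].nunique() == 1
        assert table["p_female"].nunique() == 1
        assert summary["duration_range_days"][0] == summary["duration_range_days"][1]

    def test_post_tsp_warming_changes_duration_not_sex(self):
        """Warming applied only after the TSP shifts hatch timing but leaves
        the sex prediction untouched (the window isolates it)."""
        n = 24 * 70
        base = np.full(n, 30.0)
        rate = DevRateCurve(t_opt=33.5, r_max=1.8 / 24, sigma_below=6.0, sigma_above=2.5)
        s = self._series(base)
        maturity, _ = integrate_development(s, rate)
        m = maturity.to_numpy()
        warmed = base.copy()
        warmed[m >= 67.0] += 1.5  # strictly after the TSP
        frames = pd.DataFrame({0: base, 1: warmed}, index=s.index)
        table, _ = predict_all(_FakeResult(frames), rate=rate)
        assert table.loc[0, "p_female"] == pytest.approx(table.loc[1, "p_female"], abs=1e-9)
        assert table.loc[1, "duration_days"] < table.loc[0, "duration_days"]

    def test_sand_corrections_monotone_for_negative_shape(self):
        n = 24 * 60 + 1
        sand = self._series(np.full(n, 30.5))
        frames = pd.DataFrame({0: np.full(n, 31.0)}, index=sand.index)
        _, summary = predict_all(_FakeResult(frames), sand_series=sand)
        p = [summary[k]["p_female"] for k in ("sand", "sand+0.5", "sand+1", "sand+1.5")]
        assert p == sorted(p)

    def test_duration_nonmonotone_around_rate_peak(self):
        """Below the optimum warmer means faster; above it, slower."""
        rate = DevRateCurve()
        n = 24 * 90
        durations = {}
        for t in (30.0, 33.5, 36.5):
            frames = pd.DataFrame({0: np.full(n, t)},
                                  index=self._series(np.zeros(n)).index)
            table, _ = predict_all(_FakeResult(frames), rate=rate)
            durations[t] = table.loc[0, "duration_days"]
        assert durations[33.5] < durations[30.0]
        assert durations[33.5] < durations[36.5]

    def test_unhatched_embryo_reported_without_duration(self):
        n = 24 * 20  # far too short to hatch
        frames = pd.DataFrame({0: np.full(n, 30.0)},
                              index=self._series(np.zeros(n)).index)
        table, summary = predict_all(_FakeResult(frames))
        assert np.isnan(table.loc[0, "duration_days"])
        assert summary["n_hatched"] == 0

    def test_spread_ordering_below_peak(self):
        """With all means below the rate optimum the warmest egg hatches
        first."""
        n = 24 * 80
        idx = self._series(np.zeros(n)).index
        frames = pd.DataFrame(
            {e: np.full(n, 29.5 + 0.5 * e) for e in range(4)}, index=idx
        )
        table, _ = predict_all(_FakeResult(frames))
        d = table["duration_days"].to_numpy()
        assert np.all(np.diff(d) < 0)
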