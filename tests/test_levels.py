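"""Level metrics: energetic averaging, windows, events, Intermittency Ratio."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noisescape.config import AnalysisConfig
from noisescape.levels import (
    aggregate_hourly,
    daily_metrics,
    detect_events,
    energetic_average,
    intermittency_ratio,
    metrics_table,
    period_level,
    window_levels,
)
from tests.conftest import full_day_series, ir_bruteforce, laeq_bruteforce, make_series


class TestEnergeticAverage:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            ([60.0, 60.0, 60.0], 60.0),
            ([60.0, 70.0], 10 * np.log10((1e6 + 1e7) / 2)),  # 67.40 dBA
            ([43.7], 43.7),
        ],
    )
    def test_worked_examples(self, levels, expected):
        assert energetic_average(levels) == pytest.approx(expected, abs=1e-9)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="no observations"):
            energetic_average([])

    @given(st.lists(st.floats(30, 90), min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_jensen(self, levels):
        laeq = energetic_average(levels)
        assert min(levels) - 1e-9 <= laeq <= max(levels) + 1e-9
        assert laeq >= np.mean(levels) - 1e-9

    def test_stable_at_extreme_levels(self):
        # naive 10**(L/10) sums overflow well before 4000 dB
        assert energetic_average([4000.0, 4000.0]) == pytest.approx(4000.0)


class TestEvents:
    def test_single_loud_minute_flagged(self):
        levels = [50.0] * 9 + [70.0]
        laeq = energetic_average(levels)
        assert laeq == pytest.approx(10 * np.log10(1.09e6), abs=1e-9)  # 60.37 dBA
        mask = detect_events(levels, laeq, 3.0)
        assert mask.sum() == 1 and mask[-1]

    def test_constant_series_has_no_events(self):
        levels = [55.0] * 60
        mask = detect_events(levels, energetic_average(levels), 3.0)
        assert not mask.any()

    def test_boundary_is_strict(self):
        # a minute exactly at LAeq + K must not be an event
        laeq = 60.0
        mask = detect_events([63.0, 63.0 + 1e-9], laeq, 3.0)
        assert list(mask) == [False, True]

    @given(st.lists(st.floats(30, 90), min_size=1, max_size=300))
    @settings(derandomize=True, max_examples=100)
    def test_some_minute_always_below_threshold(self, levels):
        # the energetic mean lies within the level range, so for K > 0
        # at least one minute is a non-event
        laeq = energetic_average(levels)
        assert (~detect_events(levels, laeq, 0.5)).sum() >= 1


class TestIntermittencyRatio:
    def test_worked_example(self):
        levels = [50.0] * 9 + [70.0]
        assert intermittency_ratio(levels, 3) == pytest.approx(100 * 1e7 / 1.09e7, abs=1e-9)

    def test_constant_series_zero(self):
        assert intermittency_ratio([62.0] * 1440, 3) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(1, 1441)
            levels = rng.uniform(30, 90, n)
            for k in (3, 4, 5):
                assert intermittency_ratio(levels, k) == pytest.approx(
                    ir_bruteforce(levels, k), abs=1e-9
                )

    @given(st.lists(st.floats(30, 90), min_size=2, max_size=500))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_cutoff_and_bounded(self, levels):
        irs = [intermittency_ratio(levels, k) for k in (3, 4, 5)]
        assert irs[0] >= irs[1] >= irs[2]
        for ir in irs:
            assert 0.0 <= ir < 100.0

    @given(
        st.lists(st.floats(30, 90), min_size=2, max_size=500),
        st.floats(-20, 20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_shift_equivariance(self, levels, c):
        # +c dB on every minute shifts LAeq by c and leaves IR unchanged
        shifted = [lv + c for lv in levels]
        assert energetic_average(shifted) == pytest.approx(
            energetic_average(levels) + c, abs=1e-6
        )
        assert intermittency_ratio(shifted, 3) == pytest.approx(
            intermittency_ratio(levels, 3), abs=1e-6
        )

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.2, 0.4])
    @pytest.mark.parametrize("delta", [6.0, 10.0, 15.0])
    def test_two_level_closed_form(self, p, delta):
        """Fraction p of minutes at L+delta, rest at L: IR has a closed form
        when the high level clears the threshold and the low level does not."""
        n = 1000
        n_hi = int(round(p * n))
        levels = [60.0 + delta] * n_hi + [60.0] * (n - n_hi)
        p_real = n_hi / n
        r = 10 ** (delta / 10)
        expected = 100 * p_real * r / (p_real * r + 1 - p_real)
        laeq = energetic_average(levels)
        if not (60.0 + delta > laeq + 3 and 60.0 <= laeq + 3):
            pytest.skip("closed form needs the high level above threshold, low below")
        assert intermittency_ratio(levels, 3) == pytest.approx(expected, abs=1e-9)


class TestWindows:
    def test_constant_day(self, config):
        s = full_day_series([55.0] * 1440)
        for window in ("full", "day", "night"):
            lv, cov = period_level(s, date(2021, 3, 1), window, config)
            assert lv == pytest.approx(55.0) and cov == 1.0

    def test_day_night_partition(self, config):
        levels = np.where(
            (np.arange(1440) // 60 >= 6) & (np.arange(1440) // 60 <= 21), 60.0, 50.0
        )
        s = full_day_series(levels)
        d = date(2021, 3, 1)
        assert period_level(s, d, "day", config)[0] == pytest.approx(60.0)
        assert period_level(s, d, "night", config)[0] == pytest.approx(50.0)
        n_day = len(window_levels(s, d, "day", config))
        n_night = len(window_levels(s, d, "night", config))
        assert n_day == 960 and n_night == 480

    def test_one_loud_hour_oracle(self, config):
        levels = np.full(1440, 50.0)
        levels[6 * 60 : 7 * 60] = 70.0
        s = full_day_series(levels)
        expected = 10 * np.log10((1380 * 1e5 + 60 * 1e7) / 1440)  # ~57.16 dBA
        assert period_level(s, date(2021, 3, 1), "full", config)[0] == pytest.approx(
            expected, abs=1e-9
        )

    def test_low_coverage_marks_missing(self, config):
        s = make_series([60.0] * 100)  # 100 of 1440 minutes
        lv, cov = period_level(s, date(2021, 3, 1), "full", config)
        assert lv is None and cov == pytest.approx(100 / 1440)

    def test_spanning_night_convention(self):
        cfg = AnalysisConfig(night_convention="spanning")
        # 22:00 of D at 70 dBA, early morning of D+1 at 50 dBA
        ts = pd.date_range("2021-03-01 22:00", periods=480, freq="min")
        from noisescape.types import MinuteLevelSeries

        levels = np.where(np.asarray(ts.hour) >= 22, 70.0, 50.0)
        s = MinuteLevelSeries("S1", ts, levels)
        lv = window_levels(s, date(2021, 3, 1), "night", cfg)
        assert len(lv) == 480 and (lv == 70.0).sum() == 120


class TestHourly:
    def test_constant(self, config):
        s = full_day_series([62.0] * 1440)
        out = aggregate_hourly(s, date(2021, 3, 1), config)
        assert np.allclose(out, 62.0)

    def test_alternating_hour(self, config):
        levels = np.full(1440, 50.0)
        levels[:60] = np.where(np.arange(60) % 2 == 0, 50.0, 70.0)
        s = full_day_series(levels)
        out = aggregate_hourly(s, date(2021, 3, 1), config)
        assert out[0] == pytest.approx(10 * np.log10((30 * 1e5 + 30 * 1e7) / 60), abs=1e-9)
        assert np.allclose(out[1:], 50.0)

    def test_sparse_hour_missing(self, config):
        s = make_series([60.0] * 10, start="2021-03-01 05:00")
        out = aggregate_hourly(s, date(2021, 3, 1), config)
        assert np.isnan(out[5]) and np.isnan(out).all()


class TestDailyMetrics:
    def test_constant_week_all_irs_zero(self, config):
        ts = pd.date_range("2021-03-01", periods=7 * 1440, freq="min")
        from noisescape.types import MinuteLevelSeries

        s = MinuteLevelSeries("S1", ts, np.full(7 * 1440, 58.0))
        table = metrics_table([s], config)
        assert len(table) == 7
        assert np.allclose(table["laeq_24hr"], 58.0)
        for k in (3, 4, 5):
            assert (table[f"ir_24hr_k{k}"] == 0).all()

    def test_injected_event_matches_oracle(self, config):
        levels = np.full(1440, 50.0)
        levels[600:610] = 65.0  # 10-min, 15 dB event
        s = full_day_series(levels)
        m = daily_metrics(s, date(2021, 3, 1), config)
        assert m.ir_24hr[3] == pytest.approx(ir_bruteforce(levels, 3), abs=1e-9)
        assert m.ir_day[3] == pytest.approx(
            ir_bruteforce(levels[6 * 60 : 22 * 60], 3), abs=1e-9
        )
        assert m.laeq_24hr == pytest.approx(laeq_bruteforce(levels), abs=1e-9)

    def test_missing_night_propagates(self, config):
        # observations only 06:00-21:59
        ts = pd.date_range("2021-03-01 06:00", periods=960, freq="min")
        from noisescape.types import MinuteLevelSeries

        s = MinuteLevelSeries("S1", ts, np.full(960, 60.0))
        m = daily_metrics(s, date(2021, 3, 1), config)
        assert m.l_night is None and m.ir_night[3] is None
        assert m.l_day == pytest.approx(60.0)
        assert m.coverage["night"] == 0.0

    def test_laeq_within_minute_range(self, config):
        rng = np.random.default_rng(7)
        levels = rng.uniform(40, 80, 1440)
        s = full_day_series(levels)
        m = daily_metrics(s, date(2021, 3, 1), config)
        for v, window in ((m.laeq_24hr, "full"), (m.l_day, "day"), (m.l_night, "night")):
            lv = window_levels(s, date(2021, 3, 1), window, config)
            assert lv.min() <= v <= lv.max()
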