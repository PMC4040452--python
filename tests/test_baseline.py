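"""Exclusions, diel pooling against two-pass oracles, drift OLS, event flags."""

from __future__ import annotations

from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from flowmon.assembly import ALL_COLUMNS, MultiSeries, make_grid
from flowmon.baseline import (
    DielProfile,
    EmptyBaselineError,
    ExclusionSpec,
    apply_exclusions,
    baseline_stats,
    estimate_night_drift,
    flag_events,
    pool_diel,
)

START = datetime(2013, 8, 12)  # a Monday


def series_from(values: pd.Series) -> MultiSeries:
    frame = pd.DataFrame(index=values.index, columns=list(ALL_COLUMNS), dtype=float)
    frame["tcc"] = values
    return MultiSeries(frame=frame)


def flat_series(days: int, value: float = 100.0) -> MultiSeries:
    grid = make_grid(START, START + timedelta(days=days))
    return series_from(pd.Series(value, index=grid))


class TestExclusions:
    def test_no_spec_is_identity(self):
        s = flat_series(2)
        out = apply_exclusions(s, ExclusionSpec())
        pd.testing.assert_frame_equal(out.frame, s.frame)

    def test_hand_counted_calendar(self):
        # 14 days from a Monday; exclude days 5-6 and 11-13 (0-based) plus
        # weekends; enumerate the expectation independently slot by slot
        s = flat_series(14)
        windows = [
            (START + timedelta(days=5), START + timedelta(days=7)),
            (START + timedelta(days=11), START + timedelta(days=14)),
        ]
        out = apply_exclusions(s, ExclusionSpec(windows=windows, weekdays_only=True))
        expected = 0
        for i in range(14 * 96):
            t = START + timedelta(minutes=15 * i)
            in_window = any(a <= t < b for a, b in windows)
            if not in_window and t.weekday() < 5:
                expected += 1
        assert len(out.frame) == expected
        # days 0-4 (Mon-Fri), 7-10 (Mon-Thu): 9 full weekdays
        assert expected == 9 * 96

    def test_empty_result_is_error(self):
        s = flat_series(1)
        with pytest.raises(EmptyBaselineError):
            apply_exclusions(
                s, ExclusionSpec(windows=[(START, START + timedelta(days=2))])
            )


class TestPoolDiel:
    def test_constant_series(self):
        prof = pool_diel(flat_series(3, 42.0), "tcc")
        assert (prof.bins["mean"] == 42.0).all()
        assert (prof.bins["se"] == 0.0).all()
        assert prof.overall_mean == 42.0
        assert prof.overall_n == 3 * 96

    def test_two_day_toy_bin(self):
        grid = make_grid(START, START + timedelta(days=2))
        vals = pd.Series(np.nan, index=grid)
        vals[START + timedelta(hours=6)] = 10.0
        vals[START + timedelta(days=1, hours=6)] = 12.0
        prof = pool_diel(series_from(vals), "tcc")
        row = prof.bins.loc[360]
        assert row["mean"] == pytest.approx(11.0)
        assert row["se"] == pytest.approx(1.0)  # SD = sqrt(2), SE = sqrt(2)/sqrt(2)
        assert row["n"] == 2

    def test_pooling_conserves_n_and_se_matches_two_pass_oracle(self):
        rng = np.random.default_rng(21)
        grid = make_grid(START, START + timedelta(days=5))
        vals = pd.Series(rng.normal(100, 8, len(grid)), index=grid)
        vals.iloc[rng.choice(len(grid), 40, replace=False)] = np.nan
        prof = pool_diel(series_from(vals), "tcc")
        assert prof.bins["n"].sum() == vals.count() == prof.overall_n
        for minute in (0, 255, 720, 1425):
            sel = vals[(vals.index.hour * 60 + vals.index.minute) == minute].dropna()
            mean = sum(sel) / len(sel)
            sd = np.sqrt(sum((v - mean) ** 2 for v in sel) / (len(sel) - 1))
            assert prof.bins.loc[minute, "mean"] == pytest.approx(mean)
            assert prof.bins.loc[minute, "se"] == pytest.approx(sd / np.sqrt(len(sel)))

    def test_sparse_bin_has_no_se(self):
        grid = make_grid(START, START + timedelta(days=1))
        vals = pd.Series(np.nan, index=grid)
        vals.iloc[4] = 5.0
        prof = pool_diel(series_from(vals), "tcc")
        assert np.isnan(prof.bins.iloc[4]["se"])
        assert prof.bins.iloc[4]["n"] == 1


class TestBaselineStats:
    def test_tiny_exact(self):
        grid = make_grid(START, START + timedelta(minutes=45))
        m, sd, n = baseline_stats(series_from(pd.Series([1.0, 2.0, 3.0], index=grid)), "tcc")
        assert (m, sd, n) == (2.0, 1.0, 3)

    def test_single_value(self):
        grid = make_grid(START, START + timedelta(minutes=15))
        m, sd, n = baseline_stats(series_from(pd.Series([5.0], index=grid)), "tcc")
        assert m == 5.0 and n == 1 and np.isnan(sd)

    def test_empty_errors(self):
        with pytest.raises(EmptyBaselineError):
            baseline_stats(series_from(pd.Series(np.nan, index=make_grid(START, START + timedelta(hours=1)))), "tcc")


def profile_from_values(values: np.ndarray) -> DielProfile:
    bins = pd.DataFrame(
        {"mean": values, "se": 0.0, "n": 5.0}, index=pd.Index(range(0, 1440, 15))
    )
    return DielProfile("tcc", bins, float(np.nanmean(values)), 1.0, 96 * 5)


class TestNightDrift:
    def test_exact_line_slope_recovered(self):
        minutes = np.arange(0, 1440, 15)
        # slope 2/h across the wrapped 20:00-08:00 window
        hours_since_20 = ((minutes / 60.0) - 20.0) % 24.0
        vals = np.where(hours_since_20 < 12.0, 2.0 * hours_since_20, 0.0)
        assert estimate_night_drift(profile_from_values(vals)) == pytest.approx(2.0)

    def test_flat_profile(self):
        assert estimate_night_drift(profile_from_values(np.full(96, 7.0))) == 0.0

    def test_five_point_closed_form_ols(self):
        vals = np.full(96, np.nan)
        pairs = {1200: 3.0, 1260: 4.5, 1320: 4.0, 1380: 6.0, 60: 9.0}  # clock minutes
        for m, v in pairs.items():
            vals[m // 15] = v
        bins = pd.DataFrame({"mean": vals, "se": 0.0, "n": np.where(np.isfinite(vals), 3.0, 0.0)},
                            index=pd.Index(range(0, 1440, 15)))
        prof = DielProfile("tcc", bins, np.nan, 1.0, 15)
        # hand OLS on (hours since 20:00 at mid-bin, value)
        x = np.array([0.125, 1.125, 2.125, 3.125, 5.125])
        y = np.array([3.0, 4.5, 4.0, 6.0, 9.0])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert estimate_night_drift(prof) == pytest.approx(slope)

    def test_too_few_bins_error(self):
        vals = np.full(96, np.nan)
        vals[84] = 1.0  # 21:00 only
        bins = pd.DataFrame({"mean": vals, "se": 0.0, "n": np.where(np.isfinite(vals), 2.0, 0.0)},
                            index=pd.Index(range(0, 1440, 15)))
        with pytest.raises(ValueError):
            estimate_night_drift(DielProfile("tcc", bins, np.nan, 1.0, 2))


class TestFlagEvents:
    def _baseline_profile(self, value=100.0, sd=5.0):
        bins = pd.DataFrame(
            {"mean": value, "se": 0.0, "n": 10.0}, index=pd.Index(range(0, 1440, 15))
        )
        return DielProfile("tcc", bins, value, sd, 960)

    def test_series_matching_profile_has_no_events(self):
        assert flag_events(flat_series(3, 100.0), self._baseline_profile()) == []

    def test_injected_step_detected_exactly(self):
        s = flat_series(2, 100.0)
        idx = s.frame.index
        s.frame.loc[idx[50:60], "tcc"] = 100.0 + 5 * 5.0  # +5 SD for 10 slots
        events = flag_events(s, self._baseline_profile(), k=3, m=4)
        assert len(events) == 1
        ev = events[0]
        assert ev.start == idx[50]
        assert ev.end == idx[59] + pd.Timedelta(minutes=15)
        assert ev.peak_excess_sd == pytest.approx(5.0)
        assert ev.recovery_h == pytest.approx(0.0)

    def test_short_excursion_below_m_ignored(self):
        s = flat_series(2, 100.0)
        s.frame.iloc[10:13, 0] = 200.0  # 3 slots < m=4
        assert flag_events(s, self._baseline_profile(), k=3, m=4) == []

    def test_single_missing_slot_bridged(self):
        s = flat_series(2, 100.0)
        idx = s.frame.index
        s.frame.loc[idx[30:40], "tcc"] = 150.0
        s.frame.loc[idx[35], "tcc"] = np.nan
        events = flag_events(s, self._baseline_profile(), k=3, m=4)
        assert len(events) == 1
        assert events[0].start == idx[30] and events[0].end == idx[39] + pd.Timedelta(minutes=15)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(33)
        s = flat_series(4, 100.0)
        s.frame["tcc"] += rng.normal(0, 12, len(s.frame))
        prof = self._baseline_profile(100.0, 5.0)

        def anomalous_slots(k):
            return {
                t
                for e in flag_events(s, prof, k=k, m=1)
                for t in pd.date_range(e.start, e.end - pd.Timedelta(minutes=15), freq="15min")
            }

        assert anomalous_slots(3.0) <= anomalous_slots(2.0) <= anomalous_slots(1.0)

    def test_negative_deviations_also_flagged(self):
        s = flat_series(2, 100.0)
        s.frame.iloc[20:30, 0] = 100.0 - 40.0
        events = flag_events(s, self._baseline_profile(), k=3, m=4)
        assert len(events) == 1
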