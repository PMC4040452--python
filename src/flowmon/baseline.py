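"""Baseline extraction, diel (24-h) profiles, night drift and event flagging.

A monitoring campaign is summarized by (i) a baseline subset — the slots
outside known events and, for weekly-patterned systems, outside weekends —
described by mean ± sample SD; (ii) a diel profile: all baseline values
pooled into 96 wall-clock 15-min bins across days, with per-bin mean and
standard error; and (iii) events: sustained excursions of a parameter
beyond the baseline band around its diel expectation.

Two mechanisms coexist deliberately: explicit exclusion windows reproduce a
curated analysis (events chosen by inspection), while :func:`flag_events`
is an objective detector (k standard deviations for at least m consecutive
slots). They are independent and can be cross-checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import GRID_STEP, MultiSeries

BINS_PER_DAY = 96
NIGHT_WINDOW = (time(20, 0), time(8, 0))  # default drift window, wraps midnight


class EmptyBaselineError(ValueError):
    """Raised when exclusions leave no data to summarize."""


@dataclass
class ExclusionSpec:
    """Datetime windows to drop, plus an optional weekday-only restriction."""

    windows: Sequence[tuple[datetime, datetime]] = ()
    weekdays_only: bool = False

    def __post_init__(self) -> None:
        for s, e in self.windows:
            if not s < e:
                raise ValueError(f"exclusion window not ordered: {s} >= {e}")


@dataclass
class DielProfile:
    """96-bin wall-clock profile of one parameter.

    ``bins`` is indexed by minutes-after-midnight of each 15-min bin start
    (0, 15, ..., 1425) and has columns mean, se, n; se is NaN where n < 2.
    Overall statistics are over all pooled values, not over bin means.
    """

    parameter: str
    bins: pd.DataFrame
    overall_mean: float
    overall_sd: float
    overall_n: int

    def bin_mean_at(self, ts: pd.Timestamp) -> float:
        key = ts.hour * 60 + ts.minute
        return float(self.bins.at[key, "mean"]) if key in self.bins.index else np.nan


@dataclass
class EventWindow:
    """One sustained excursion beyond the baseline band."""

    parameter: str
    start: pd.Timestamp
    end: pd.Timestamp  # end of the last anomalous slot
    peak_value: float
    peak_excess_sd: float  # |peak - diel expectation| in baseline SDs
    recovery_h: float  # trigger end -> first observed in-band slot

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event window must have start < end")


def apply_exclusions(series: MultiSeries, spec: ExclusionSpec) -> MultiSeries:
    """Drop slots inside any exclusion window (and weekends, if requested)."""
    idx = series.frame.index
    keep = np.ones(len(idx), dtype=bool)
    for s, e in spec.windows:
        keep &= ~((idx >= pd.Timestamp(s)) & (idx < pd.Timestamp(e)))
    if spec.weekdays_only:
        keep &= idx.dayofweek < 5
    if not keep.any():
        raise EmptyBaselineError("exclusions removed every slot")
    return MultiSeries(frame=series.frame.loc[keep], meta=dict(series.meta))


def pool_diel(subset: MultiSeries, parameter: str) -> DielProfile:
    """Pool all days of ``parameter`` into 96 wall-clock 15-min bins.

    Per bin: arithmetic mean, SE = sample SD / sqrt(n) (undefined below
    n = 2) and n. Pooling conserves data: the bin counts sum to the number
    of non-missing values in the subset.
    """
    vals = subset.frame[parameter].dropna()
    minutes = vals.index.hour * 60 + vals.index.minute
    bin_index = pd.Index(range(0, 1440, 15), name="minute_of_day")
    grouped = vals.groupby(minutes)
    bins = pd.DataFrame(index=bin_index, columns=["mean", "se", "n"], dtype=float)
    bins["n"] = 0.0
    if len(vals):
        agg = grouped.agg(["mean", "std", "count"])
        bins.loc[agg.index, "mean"] = agg["mean"].to_numpy()
        bins.loc[agg.index, "se"] = (agg["std"] / np.sqrt(agg["count"])).to_numpy()
        bins.loc[agg.index, "n"] = agg["count"].to_numpy(dtype=float)
    overall_sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return DielProfile(
        parameter=parameter,
        bins=bins,
        overall_mean=float(vals.mean()) if len(vals) else np.nan,
        overall_sd=overall_sd,
        overall_n=int(len(vals)),
    )


def baseline_stats(subset: MultiSeries, parameter: str) -> tuple[float, float, int]:
    """(mean, sample SD, n) of the non-missing values of one parameter."""
    vals = subset.frame[parameter].dropna()
    if not len(vals):
        raise EmptyBaselineError(f"no data for {parameter}")
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return float(vals.mean()), sd, int(len(vals))


def _window_minutes(window: tuple[time, time]) -> list[int]:
    """Bin-start minutes inside a clock window, unwrapped past midnight."""
    start = window[0].hour * 60 + window[0].minute
    end = window[1].hour * 60 + window[1].minute
    if end > start:
        return list(range(start, end, 15))
    return list(range(start, 1440, 15)) + list(range(0, end, 15))


def estimate_night_drift(
    profile: DielProfile, window: tuple[time, time] = NIGHT_WINDOW
) -> float:
    """OLS slope (units/h) of diel bin means across a clock window.

    The window may wrap midnight; times are unwrapped so the regression
    runs over a contiguous axis (hours since window start, at bin
    mid-times).
    """
    minutes = _window_minutes(window)
    x, y = [], []
    for offset_idx, m in enumerate(minutes):
        row = profile.bins.loc[m]
        if row["n"] >= 1 and np.isfinite(row["mean"]):
            x.append(offset_idx * 0.25 + 0.125)  # h since window start, mid-bin
            y.append(row["mean"])
    if len(x) < 2:
        raise ValueError("night-drift window covers fewer than 2 usable bins")
    res = stats.linregress(x, y)
    return float(res.slope)


def flag_events(
    series: MultiSeries,
    profile: DielProfile,
    k: float = 3.0,
    m: int = 4,
) -> list[EventWindow]:
    """Detect sustained deviations from the diel baseline.

    A slot is anomalous when |value − diel-bin mean| > k × overall baseline
    SD. Runs of at least ``m`` consecutive anomalous slots become events;
    single missing slots inside a run are bridged, and runs separated by
    fewer than ``m`` in-band slots are merged — the detector cannot resolve
    two excursions closer than its own minimum duration, so a brief return
    to the band inside one physical excursion does not split it. Recovery
    time is measured from the end of the last anomalous slot to the start
    of the first observed in-band slot.
    """
    if k <= 0 or m < 1:
        raise ValueError("need k > 0 and m >= 1")
    frame = series.frame
    vals = frame[profile.parameter]
    expect = np.array([profile.bin_mean_at(t) for t in frame.index])
    dev = (vals.to_numpy() - expect) / profile.overall_sd
    anomalous = np.abs(dev) > k  # NaN compares False: missing is not anomalous
    observed = np.isfinite(vals.to_numpy()) & np.isfinite(expect)

    runs: list[list[int]] = []
    current: list[int] = []
    gap = 0
    for i in range(len(frame)):
        if anomalous[i]:
            current.append(i)
            gap = 0
        elif current and not observed[i] and gap < 1:
            gap += 1  # bridge a single missing slot
        else:
            if current:
                runs.append(current)
            current, gap = [], 0
    if current:
        runs.append(current)

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] - 1 < m:
            merged[-1] = merged[-1] + run
        else:
            merged.append(run)

    events: list[EventWindow] = []
    for run in merged:
        if len(run) < m:
            continue
        idx = frame.index
        seg = run[int(np.argmax(np.abs(dev[run])))]
        last = run[-1]
        recovery_h = np.nan
        for j in range(last + 1, len(frame)):
            if observed[j] and not anomalous[j]:
                recovery_h = (idx[j] - (idx[last] + GRID_STEP)) / pd.Timedelta(hours=1)
                break
        events.append(
            EventWindow(
                parameter=profile.parameter,
                start=idx[run[0]],
                end=idx[last] + GRID_STEP,
                peak_value=float(vals.iloc[seg]),
                peak_excess_sd=float(abs(dev[seg])),
                recovery_h=float(recovery_h),
            )
        )
    return events


def diel_profile_frame(profile: DielProfile) -> pd.DataFrame:
    """Export layout for a diel profile (one row per clock bin)."""
    out = profile.bins.copy()
    out.insert(0, "clock", [f"{m // 60:02d}:{m % 60:02d}" for m in out.index])
    return out
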