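"""Assembly of FCM summaries, sensor channels and rainfall onto a 15-min grid.

The cytometer samples every 15 min while the abiotic sensors log every 10 s,
so the sensor channels are reduced to one value per 15-min window (the mean
of valid records in the left-closed window [t, t+15min)) and rainfall — a
flux, not a state — is summed per window. Gaps are represented as missing
values on a strictly regular grid, never as irregular spacing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fcs_io import RainfallLog, SensorLog
from .gating import SampleSummary

GRID_STEP = pd.Timedelta(minutes=15)
FCM_COLUMNS = ("tcc", "pct_lna")
SENSOR_COLUMNS = ("T", "DO", "EC", "pH")
ALL_COLUMNS = FCM_COLUMNS + SENSOR_COLUMNS + ("rain",)


class AlignmentError(ValueError):
    """Raised when inputs do not share the expected grid."""


@dataclass
class MultiSeries:
    """Time-aligned campaign table: one row per 15-min slot.

    ``frame`` is indexed by the grid timestamps and has columns tcc,
    pct_lna, T, DO, EC, pH, rain; missing values are NaN (rain defaults to
    0 where a rain log was joined). ``meta`` carries campaign metadata
    (site, start, end).
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.frame.index
        if len(idx) > 1:
            deltas = np.unique(np.diff(idx.asi8))
            if (deltas <= 0).any() or (deltas % GRID_STEP.value != 0).any():
                raise AlignmentError(
                    "timestamps must be strictly increasing on the 15-min grid"
                )

    @property
    def is_contiguous(self) -> bool:
        """True when the grid has no dropped rows (gaps are NaN, not absent)."""
        idx = self.frame.index
        if len(idx) < 2:
            return True
        return bool((np.diff(idx.asi8) == GRID_STEP.value).all())

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="timestamp")
        sidecar = Path(path).with_suffix(".meta.json")
        with open(sidecar, "w") as fh:
            json.dump({k: str(v) for k, v in self.meta.items()}, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MultiSeries":
        frame = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
        sidecar = Path(path).with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame=frame, meta=meta)


def make_grid(start, end) -> pd.DatetimeIndex:
    """Regular 15-min timestamps covering [start, end)."""
    return pd.date_range(start, end, freq="15min", inclusive="left")


def assemble_fcm_series(
    summaries: Sequence[SampleSummary],
    grid: pd.DatetimeIndex | None = None,
) -> MultiSeries:
    """Snap per-sample summaries onto the 15-min grid.

    Each summary is assigned to the nearest grid slot (within half an
    interval); when two summaries land on one slot the earliest is kept and
    a warning is emitted. Slots without a sample stay missing.
    """
    ts = pd.DatetimeIndex([s.timestamp for s in summaries])
    if grid is None:
        if not len(ts):
            raise AlignmentError("no summaries and no explicit grid")
        grid = make_grid(ts.min().floor("15min"), ts.max().ceil("15min") + GRID_STEP)
    frame = pd.DataFrame(index=grid, columns=list(ALL_COLUMNS), dtype=float)
    order = np.argsort(ts.asi8, kind="stable")
    filled: dict[pd.Timestamp, pd.Timestamp] = {}
    for i in order:
        s = summaries[i]
        t = pd.Timestamp(s.timestamp)
        slot = t.round("15min")
        # pandas rounds ties to even; the contract wants ties at the earlier slot
        if (t - slot.floor("15min")) == GRID_STEP / 2:
            slot = t.floor("15min")
            warnings.warn(f"summary {s.sample_id} equidistant to two slots; using earlier")
        if abs(t - slot) > GRID_STEP / 2 or slot not in frame.index:
            warnings.warn(f"summary {s.sample_id} at {t} has no grid slot; skipped")
            continue
        if slot in filled:
            warnings.warn(f"duplicate sample for slot {slot}; keeping earliest")
            continue
        filled[slot] = t
        frame.at[slot, "tcc"] = s.tcc
        frame.at[slot, "pct_lna"] = s.pct_lna
    return MultiSeries(frame=frame, meta={"start": grid[0], "end": grid[-1] + GRID_STEP})


def downsample_sensors(log: SensorLog, grid: pd.DatetimeIndex) -> pd.DataFrame:
    """Mean of valid sensor records per left-closed 15-min window.

    Windows with no valid record are missing. The aggregation statistic is
    the window mean (noise suppression over snapshot sampling).
    """
    rec = log.records
    out = pd.DataFrame(index=grid, columns=list(SENSOR_COLUMNS), dtype=float)
    if not len(rec):
        return out
    valid = rec[rec["valid"]].copy()
    slot = valid["timestamp"].dt.floor("15min")
    grouped = valid.groupby(slot)[list(SENSOR_COLUMNS)].mean()
    common = grouped.index.intersection(grid)
    out.loc[common] = grouped.loc[common].to_numpy()
    return out


def window_rainfall(rain: RainfallLog, grid: pd.DatetimeIndex) -> pd.Series:
    """Sum rainfall into each 15-min window (conserving total volume)."""
    out = pd.Series(0.0, index=grid)
    rec = rain.records
    if not len(rec):
        return out
    slot = rec["timestamp"].dt.floor("15min")
    sums = rec.groupby(slot)["rain"].sum()
    common = sums.index.intersection(grid)
    out.loc[common] = sums.loc[common].to_numpy()
    return out


def join_series(
    fcm: MultiSeries,
    sensors: pd.DataFrame | None = None,
    rain: RainfallLog | None = None,
) -> MultiSeries:
    """Merge FCM, sensor and rainfall data on a shared grid."""
    frame = fcm.frame.copy()
    if sensors is not None:
        if not sensors.index.equals(frame.index):
            raise AlignmentError("sensor grid does not match the FCM grid")
        frame[list(SENSOR_COLUMNS)] = sensors[list(SENSOR_COLUMNS)]
    if rain is not None:
        frame["rain"] = window_rainfall(rain, frame.index)
    return MultiSeries(frame=frame, meta=dict(fcm.meta))
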