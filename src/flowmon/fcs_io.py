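"""Reading and writing of flow-cytometry event files and sensor/rainfall logs.

The online cytometer produces one FCS file per 15-min sample with four
pulse-height channels: FL1-H (green fluorescence, the nucleic-acid stain
signal), FL3-H (red fluorescence), FSC-H and SSC-H (forward/side scatter).
This module implements a minimal FCS 3.0/3.1 list-mode reader and an FCS 3.1
float writer, plus CSV readers for the 10-s abiotic sensor log (temperature,
dissolved oxygen, electrical conductivity, pH) and the rainfall record.

Acquisition constants (flow rate, acquisition duration, staining dilution)
normally live in the pipeline configuration and, when given, override
whatever the file metadata claims; the instrument keywords are only a
fallback.
"""

from __future__ import annotations

import io
import re
import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical channel names, in file order
CHANNELS = ("FL1-H", "FL3-H", "FSC-H", "SSC-H")

#: default acquisition constants of the monitoring campaigns
DEFAULT_FLOW_RATE = 66.0  # µL/min
DEFAULT_DURATION = 30.0  # s
DEFAULT_DILUTION = 2.0  # 1:1 sample:stain mixing

_HEADER_LEN = 58
_DELIM = "/"


class FcsFormatError(ValueError):
    """Raised when a file is not parseable FCS or lacks a required channel."""


class FcsMetadataError(ValueError):
    """Raised when required acquisition metadata cannot be determined."""


class SensorLogError(ValueError):
    """Raised for structurally invalid sensor/rainfall logs."""


@dataclass
class FcmSample:
    """One acquisition: per-event channel values plus acquisition metadata.

    ``events`` is a DataFrame with one row per detected event and one column
    per channel in :data:`CHANNELS`; values are nonnegative arbitrary
    fluorescence/scatter units. ``dilution_factor`` is the total sample
    dilution introduced by staining (2.0 for 1:1 mixing with the dye
    solution), so that concentrations can be reported for the unstained
    sample.
    """

    sample_id: str
    timestamp: datetime
    events: pd.DataFrame
    flow_rate: float = DEFAULT_FLOW_RATE  # µL/min
    duration: float = DEFAULT_DURATION  # s
    dilution_factor: float = DEFAULT_DILUTION
    instrument_threshold_channel: str = "FL1-H"
    instrument_threshold_value: float = 1000.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def analyzed_volume(self) -> float:
        """Volume of stained sample analyzed, in µL (flow_rate × duration / 60)."""
        return self.flow_rate * self.duration / 60.0

    def validate(self) -> None:
        missing = [c for c in CHANNELS if c not in self.events.columns]
        if missing:
            raise FcsFormatError(f"sample {self.sample_id!r} lacks channel(s): {missing}")
        if self.flow_rate <= 0 or self.duration <= 0:
            raise FcsMetadataError("flow_rate and duration must be positive")
        if self.dilution_factor < 1:
            raise FcsMetadataError("dilution_factor must be >= 1")
        vals = self.events[list(CHANNELS)].to_numpy()
        if vals.size:
            if not np.isfinite(vals).all():
                raise FcsFormatError("non-finite channel value in event table")
            if (vals < 0).any():
                raise FcsFormatError("negative channel value in event table")


@dataclass
class SensorLog:
    """Ordered 10-s (or similar) abiotic sensor records.

    ``records`` has a ``timestamp`` column, one column per present channel
    among T (°C), DO (mg/L), EC (µS/cm), pH, and a boolean ``valid`` column:
    rows violating physical invariants (pH outside [0, 14], negative DO/EC)
    are flagged invalid, never silently dropped.
    """

    records: pd.DataFrame
    cadence: float = 10.0  # s

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RainfallLog:
    """Ordered rainfall record; ``rain`` is mm fallen per logging interval."""

    records: pd.DataFrame

    def total(self) -> float:
        return float(self.records["rain"].sum())


# ---------------------------------------------------------------------------
# FCS writing


def _text_segment(keywords: Mapping[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(sample: FcmSample, path: str | Path) -> Path:
    """Write ``sample`` as an FCS 3.1 file (float32, list mode).

    Channel values are stored as little-endian float32, so round-trips
    preserve values to float32 precision. Acquisition metadata is stored in
    the TEXT segment (FLOWRATE, DURATION, DILFACTOR, $DATE, $BTIM).
    """
    sample.validate()
    path = Path(path)
    data = np.ascontiguousarray(
        sample.events[list(CHANNELS)].to_numpy(dtype="<f4")
    ).tobytes()
    n_events = len(sample.events)

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width so that the TEXT length does not depend on the offsets
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$NEXTDATA": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$PAR": str(len(CHANNELS)),
        "$TOT": str(n_events),
        "$DATE": sample.timestamp.strftime("%d-%b-%Y").upper(),
        "$BTIM": sample.timestamp.strftime("%H:%M:%S"),
        "SMPLID": sample.sample_id,
        "FLOWRATE": repr(sample.flow_rate),
        "DURATION": repr(sample.duration),
        "DILFACTOR": repr(sample.dilution_factor),
        "THRESHCH": sample.instrument_threshold_channel,
        "THRESHVAL": repr(sample.instrument_threshold_value),
    }
    for i, ch in enumerate(CHANNELS, start=1):
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "16777216"

    text = _text_segment(keywords)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1 if data else 0

    keywords["$BEGINDATA"] = "%012d" % (data_start if data else 0)
    keywords["$ENDDATA"] = "%012d" % data_end
    text = _text_segment(keywords)
    assert text_start + len(text) - 1 == text_end  # fixed-width invariant

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:  # too large for the header slot: signalled via TEXT
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _off(v)
        for v in (
            text_start,
            text_end,
            data_start if data else 0,
            data_end,
            0,
            0,
        )
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# FCS reading

_FNAME_TS = re.compile(r"(\d{8})[-_](\d{4})")


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    fields = raw.decode("latin-1").split(delim)[1:]
    kv: dict[str, str] = {}
    for i in range(0, len(fields) - 1, 2):
        key = fields[i].strip()
        if key:
            kv[key.upper()] = fields[i + 1]
    return kv

def _file_timestamp(kv: Mapping[str, str], path: Path) -> datetime:
    date, btim = kv.get("$DATE"), kv.get("$BTIM")
    if date and btim:
        for fmt in ("%d-%b-%Y %H:%M:%S", "%d-%b-%Y %H:%M"):
            try:
                return datetime.strptime(f"{date.title()} {btim}", fmt)
            except ValueError:
                continue
    m = _FNAME_TS.search(path.stem)
    if m:
        return datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M")
    raise FcsMetadataError(
        f"{path}: no parsable $DATE/$BTIM and no YYYYMMDD-HHMM in filename"
    )


def read_fcs(
    path: str | Path,
    *,
    aliases: Mapping[str, str] | None = None,
    flow_rate: float | None = None,
    duration: float | None = None,
    dilution_factor: float | None = None,
) -> FcmSample:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`FcmSample`.

    Parameters given as keyword arguments (the pipeline configuration path)
    override file metadata. ``aliases`` maps vendor $PnN short names to the
    canonical channel names, e.g. ``{"FL1-A": "FL1-H"}``.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN or raw[:3] != b"FCS":
        raise FcsFormatError(f"{path}: not an FCS file")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _hdr(i: int) -> int:
        s = raw[10 + 8 * i : 18 + 8 * i].decode("ascii").strip()
        return int(s) if s else 0

    t0, t1 = _hdr(0), _hdr(1)
    kv = _parse_text(raw[t0 : t1 + 1])

    d0, d1 = _hdr(2), _hdr(3)
    if d0 == 0 and "$BEGINDATA" in kv:
        d0, d1 = int(kv["$BEGINDATA"]), int(kv["$ENDDATA"])

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    names = []
    for i in range(1, n_par + 1):
        name = kv.get(f"$P{i}N", f"P{i}").strip()
        if aliases and name in aliases:
            name = aliases[name]
        names.append(name)
    missing = [c for c in CHANNELS if c not in names]
    if missing:
        raise FcsFormatError(f"{path}: missing required channel(s): {missing}")

    dtype_code = kv.get("$DATATYPE", "F").strip().upper()
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    if dtype_code == "F":
        dt = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        dt = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        bits = {kv.get(f"$P{i}B", "32").strip() for i in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FcsFormatError(f"{path}: mixed $PnB widths unsupported")
        dt = np.dtype(f"{endian}u{int(bits.pop()) // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    n_values = n_tot * n_par
    if n_values:
        buf = raw[d0 : d1 + 1]
        arr = np.frombuffer(buf, dtype=dt, count=n_values).astype(float)
        arr = arr.reshape(n_tot, n_par)
    else:
        arr = np.empty((0, n_par))
    events = pd.DataFrame(arr, columns=names)[list(CHANNELS)]

    def _meta(key: str, override: float | None, default: float) -> float:
        if override is not None:
            return float(override)
        if key in kv:
            try:
                return float(kv[key])
            except ValueError:
                pass
        return default

    return FcmSample(
        sample_id=kv.get("SMPLID", path.stem),
        timestamp=_file_timestamp(kv, path),
        events=events,
        flow_rate=_meta("FLOWRATE", flow_rate, DEFAULT_FLOW_RATE),
        duration=_meta("DURATION", duration, DEFAULT_DURATION),
        dilution_factor=_meta("DILFACTOR", dilution_factor, DEFAULT_DILUTION),
        instrument_threshold_channel=kv.get("THRESHCH", "FL1-H"),
        instrument_threshold_value=_meta("THRESHVAL", None, 1000.0),
    )


# ---------------------------------------------------------------------------
# Sensor / rainfall CSV


def read_sensor_log(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    cadence: float = 10.0,
) -> SensorLog:
    """Read a delimited sensor log into an ordered, validity-flagged SensorLog.

    ``schema`` maps file column names to canonical channels (T, DO, EC, pH);
    by default columns already named canonically are taken as-is. Rows with
    physically impossible values (pH outside [0, 14], negative DO or EC) are
    flagged ``valid=False`` but kept. Non-monotone timestamps are an error.
    """
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    ts_col = next((cols[c] for c in cols if c.lower() in ("timestamp", "time", "datetime")), None)
    if ts_col is None:
        raise SensorLogError(f"{path}: no timestamp column")
    out = pd.DataFrame({"timestamp": pd.to_datetime(df[ts_col])})
    mapping = dict(schema) if schema else {}
    for canonical in ("T", "DO", "EC", "pH"):
        src = next((k for k, v in mapping.items() if v == canonical), None)
        if src is None and canonical in cols:
            src = cols[canonical]
        out[canonical] = pd.to_numeric(df[src], errors="coerce") if src is not None else np.nan
    if out["timestamp"].size and not out["timestamp"].is_monotonic_increasing:
        bad = out.index[out["timestamp"].diff().dt.total_seconds().fillna(1) <= 0]
        raise SensorLogError(f"{path}: non-monotone timestamps at rows {list(bad)[:10]}")
    valid = pd.Series(True, index=out.index)
    valid &= ~((out["pH"] < 0) | (out["pH"] > 14))
    valid &= ~(out["DO"] < 0)
    valid &= ~(out["EC"] < 0)
    out["valid"] = valid
    return SensorLog(records=out, cadence=cadence)


def read_rainfall_log(path: str | Path) -> RainfallLog:
    """Read a rainfall CSV (timestamp, rain in mm per interval)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    ts = cols.get("timestamp") or cols.get("time")
    rain = cols.get("rain") or cols.get("rain_mm")
    if ts is None or rain is None:
        raise SensorLogError(f"{path}: need timestamp and rain columns")
    out = pd.DataFrame(
        {"timestamp": pd.to_datetime(df[ts]), "rain": pd.to_numeric(df[rain])}
    )
    if (out["rain"] < 0).any():
        raise SensorLogError(f"{path}: negative rainfall")
    if not out["timestamp"].is_monotonic_increasing:
        raise SensorLogError(f"{path}: non-monotone timestamps")
    return RainfallLog(records=out)
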