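"""Fixed-gate classification of cytometry events and concentration math.

Events are log10-transformed (floored at 1) and classified by a polygonal
total-cell gate in the (FL1-H, FL3-H) plane, separating SYBR-Green-stained
bacterial cells from instrument/background noise. Gated cells are split into
low (LNA) and high (HNA) nucleic-acid-content subpopulations by a threshold
on transformed FL1-H; %LNA is the standard one-number cytometric fingerprint
for drinking and surface water.

Gate coordinates are data, not code: they ship as a JSON file (see
``default_gate``) and can be replaced per campaign. Points on the polygon
boundary count as inside; events exactly at the LNA/HNA threshold count as
HNA. Both conventions are deterministic tie-breaks, stated once here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fcs_io import CHANNELS, FcmSample

#: below this many gated events the %LNA estimate is too noisy to trust
DEFAULT_MIN_EVENTS = 50


class GateError(ValueError):
    """Raised for degenerate or inconsistent gate definitions."""


@dataclass
class GateSet:
    """A total-cell polygon gate plus an LNA/HNA threshold.

    ``polygon`` is a list of (FL1, FL3) vertices in transformed (log10)
    coordinates; it must be simple (non-self-intersecting) with >= 3
    vertices. ``lna_hna_threshold`` is a transformed FL1-H value: gated
    events strictly below it are LNA, the rest HNA.
    """

    polygon: Sequence[tuple[float, float]]
    lna_hna_threshold: float
    transform: str = "log10_floor1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pts = np.asarray(self.polygon, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise GateError("polygon needs >= 3 (FL1, FL3) vertices")
        if _polygon_area(pts) == 0.0:
            raise GateError("degenerate polygon (zero area)")
        if _self_intersects(pts):
            raise GateError("polygon is self-intersecting")
        lo, hi = pts[:, 0].min(), pts[:, 0].max()
        if not (lo <= self.lna_hna_threshold <= hi):
            raise GateError(
                f"LNA/HNA threshold {self.lna_hna_threshold} outside the "
                f"polygon FL1 extent [{lo}, {hi}]"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GateSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            polygon=[tuple(v) for v in d["polygon"]],
            lna_hna_threshold=float(d["lna_hna_threshold"]),
            transform=d.get("transform", "log10_floor1"),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "transform": self.transform,
                    "polygon": [list(v) for v in self.polygon],
                    "lna_hna_threshold": self.lna_hna_threshold,
                },
                fh,
                indent=1,
            )


def default_gate() -> GateSet:
    """The packaged default gate for SYBR-Green-stained water samples.

    A trapezoidal total-cell region spanning log10 FL1 in [3.0, 6.5] and
    log10 FL3 in [1.0, 5.5], with the LNA/HNA split at log10 FL1 = 4.0 —
    the published convention for drinking-water SYBR Green I staining. The
    exact coordinates are a documented, versioned stand-in; real campaigns
    should ship their own gate file.
    """
    ref = resources.files("flowmon").joinpath("data/default_gate.json")
    with resources.as_file(ref) as p:
        return GateSet.from_json(p)


@dataclass
class SampleSummary:
    """Per-sample derived metrics: counts, TCC and the %LNA fingerprint."""

    sample_id: str
    timestamp: object
    n_total_events: int
    n_gated: int
    n_lna: int
    n_hna: int
    tcc: float  # cells/µL of the original (pre-stain) sample
    pct_lna: float  # % of gated cells; NaN when n_gated == 0
    analyzed_volume: float  # µL
    qc_flags: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# geometry helpers


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    return (
        orient(p1, p2, p3) * orient(p1, p2, p4) < 0
        and orient(p3, p4, p1) * orient(p3, p4, p2) < 0
    )


def _self_intersects(pts: np.ndarray) -> bool:
    n = len(pts)
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        for j in range(i + 1, n):
            if abs(i - j) <= 1 or (i == 0 and j == n - 1):
                continue
            c, d = pts[j], pts[(j + 1) % n]
            if _segments_cross(a, b, c, d):
                return True
    return False


def points_in_polygon(
    x: np.ndarray, y: np.ndarray, polygon: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Boundary-inclusive point-in-polygon test, vectorized over points.

    Crossing-number (even-odd) rule, with points lying exactly on an edge or
    vertex reported as inside regardless of the parity result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pts = np.asarray(polygon, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    on_edge = np.zeros(x.shape, dtype=bool)
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        # edge-crossing of the horizontal ray to +inf from (x, y)
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < x_int)
        # collinear and within the segment's bounding box => on the edge
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        bbox = (
            (np.minimum(x1, x2) <= x)
            & (x <= np.maximum(x1, x2))
            & (np.minimum(y1, y2) <= y)
            & (y <= np.maximum(y1, y2))
        )
        on_edge |= (cross == 0) & bbox
    return inside | on_edge


# ---------------------------------------------------------------------------
# operations


def transform_events(sample: FcmSample) -> pd.DataFrame:
    """log10-transform all channels, flooring values at 1 (so 0 maps to 0)."""
    vals = sample.events[list(CHANNELS)].to_numpy(dtype=float)
    return pd.DataFrame(
        np.log10(np.maximum(vals, 1.0)), columns=list(CHANNELS), index=sample.events.index
    )


def apply_total_cell_gate(transformed: pd.DataFrame, gate: GateSet) -> np.ndarray:
    """Boolean mask of events inside (or on the boundary of) the cell gate."""
    gate.validate()
    return points_in_polygon(
        transformed["FL1-H"].to_numpy(), transformed["FL3-H"].to_numpy(), gate.polygon
    )


def split_hna_lna(gated: pd.DataFrame, gate: GateSet) -> tuple[int, int]:
    """Count (n_lna, n_hna) among gated events; at-threshold events are HNA."""
    fl1 = gated["FL1-H"].to_numpy()
    n_lna = int((fl1 < gate.lna_hna_threshold).sum())
    return n_lna, len(fl1) - n_lna


def compute_tcc(n_gated: int, sample: FcmSample) -> float:
    """Cell concentration of the original sample, in cells/µL.

    analyzed_volume = flow_rate × duration / 60 (µL of stained mixture);
    the dilution factor undoes the 1:1 staining so the concentration refers
    to the water before dye addition.
    """
    vol = sample.analyzed_volume
    if vol <= 0:
        raise ValueError("analyzed volume must be positive")
    if n_gated < 0:
        raise ValueError("n_gated must be >= 0")
    return n_gated / vol * sample.dilution_factor


def summarize_sample(
    sample: FcmSample,
    gate: GateSet,
    min_events: int = DEFAULT_MIN_EVENTS,
    metadata_overridden: bool = False,
) -> SampleSummary:
    """Full per-sample chain: transform → gate → LNA/HNA split → TCC."""
    transformed = transform_events(sample)
    mask = apply_total_cell_gate(transformed, gate)
    gated = transformed.loc[mask]
    n_lna, n_hna = split_hna_lna(gated, gate)
    n_gated = n_lna + n_hna
    flags = set()
    if len(sample.events) == 0:
        flags.add("zero_events")
    if 0 < n_gated < min_events:
        flags.add("low_events")
    if n_gated == 0:
        flags.add("pct_lna_undefined")
    if metadata_overridden:
        flags.add("metadata_overridden")
    return SampleSummary(
        sample_id=sample.sample_id,
        timestamp=sample.timestamp,
        n_total_events=len(sample.events),
        n_gated=n_gated,
        n_lna=n_lna,
        n_hna=n_hna,
        tcc=compute_tcc(n_gated, sample),
        pct_lna=100.0 * n_lna / n_gated if n_gated else float("nan"),
        analyzed_volume=sample.analyzed_volume,
        qc_flags=frozenset(flags),
    )


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """One row per sample, in input order — the CSV export layout."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "timestamp": [s.timestamp for s in summaries],
            "n_total_events": [s.n_total_events for s in summaries],
            "n_gated": [s.n_gated for s in summaries],
            "n_lna": [s.n_lna for s in summaries],
            "n_hna": [s.n_hna for s in summaries],
            "tcc": [s.tcc for s in summaries],
            "pct_lna": [s.pct_lna for s in summaries],
            "analyzed_volume": [s.analyzed_volume for s in summaries],
            "qc_flags": [";".join(sorted(s.qc_flags)) for s in summaries],
        }
    )
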