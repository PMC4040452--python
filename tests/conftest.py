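"""Shared fixtures: small samples, tiny campaigns, and full preset runs."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from flowmon import baseline, correlate, gating, pipeline
from flowmon import synthetic_data as syn
from flowmon.fcs_io import CHANNELS, FcmSample


def make_sample(
    values: np.ndarray | None = None,
    n: int = 100,
    seed: int = 0,
    **kwargs,
) -> FcmSample:
    """An FcmSample with given (n, 4) channel values or random positives."""
    if values is None:
        rng = np.random.default_rng(seed)
        values = 10.0 ** rng.uniform(0.0, 6.0, size=(n, 4))
    events = pd.DataFrame(np.asarray(values, dtype=float), columns=list(CHANNELS))
    defaults = dict(sample_id="s1", timestamp=datetime(2013, 8, 12, 0, 0))
    defaults.update(kwargs)
    return FcmSample(events=events, **defaults)


def ray_cast_oracle(x: float, y: float, polygon) -> bool:
    """Independent pointwise ray-casting with explicit boundary handling."""
    n = len(polygon)
    on_edge = False
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if (
            cross == 0
            and min(x1, x2) <= x <= max(x1, x2)
            and min(y1, y2) <= y <= max(y1, y2)
        ):
            on_edge = True
    if on_edge:
        return True
    inside = False
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def run_preset_campaign(preset: str, seed: int) -> dict:
    """Full synthetic campaign through the measurement pipeline."""
    cfg = syn.PRESETS[preset](seed=seed)
    truth, gt = syn.simulate_campaign(cfg)
    samples = syn.generate_samples(truth, gt, cfg)
    summaries = pipeline.gate_samples(samples, gating.default_gate())
    series = pipeline.build_series(summaries, grid=truth.frame.index)
    # sensor and rain channels come from the generator's slot-level logs
    for col in ("T", "DO", "EC", "pH", "rain"):
        series.frame[col] = truth.frame[col]
    subset = baseline.apply_exclusions(series, syn.preset_exclusions(cfg))
    return {
        "config": cfg,
        "truth": truth,
        "gt": gt,
        "summaries": summaries,
        "series": series,
        "subset": subset,
    }


@pytest.fixture(scope="session")
def tap_run() -> dict:
    return run_preset_campaign("tap_published", seed=1)


@pytest.fixture(scope="session")
def river_run() -> dict:
    return run_preset_campaign("river_published", seed=1)
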