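#!/usr/bin/env python
"""Join FCM summaries, downsampled sensors and rainfall on the 15-min grid.

For each campaign: snap the per-sample summaries from
results/{site}_sample_summaries.csv onto a regular 15-min grid, reduce the
10-s sensor log to one (mean) value per window, sum rainfall per window,
and write the joined table to results/{site}_multiseries.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from flowmon import assembly, fcs_io, pipeline
from flowmon.gating import SampleSummary

ROOT = Path(__file__).resolve().parents[1]


def load_summaries(path: Path) -> list[SampleSummary]:
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        SampleSummary(
            sample_id=r.sample_id,
            timestamp=r.timestamp,
            n_total_events=r.n_total_events,
            n_gated=r.n_gated,
            n_lna=r.n_lna,
            n_hna=r.n_hna,
            tcc=r.tcc,
            pct_lna=r.pct_lna,
            analyzed_volume=r.analyzed_volume,
        )
        for r in frame.itertuples()
    ]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--campaigns", type=Path, default=ROOT / "scratch" / "campaigns")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    for site in ("tap", "river"):
        summaries = load_summaries(args.results / f"{site}_sample_summaries.csv")
        sensor_csv = args.campaigns / site / "sensors.csv"
        rain_csv = args.campaigns / site / "rain.csv"
        sensor_log = fcs_io.read_sensor_log(sensor_csv) if sensor_csv.exists() else None
        rain_log = fcs_io.read_rainfall_log(rain_csv) if rain_csv.exists() else None
        series = pipeline.build_series(summaries, sensor_log, rain_log)
        out = args.results / f"{site}_multiseries.csv"
        series.to_csv(out)
        filled = int(series.frame["tcc"].count())
        print(f"{site}: {len(series)} slots, {filled} with FCM data -> {out}")


if __name__ == "__main__":
    main()
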