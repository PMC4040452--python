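"""End-to-end campaign analysis: read -> gate -> assemble -> baseline -> correlate.

``run_pipeline`` drives the file-based workflow from a single
:class:`PipelineConfig`; the intermediate functions (:func:`gate_samples`,
:func:`build_series`, :func:`analyze_series`) are the in-memory surface
used by the analysis scripts and tests. Every stage logs its n — samples
in and summaries out must match, as must slots in and out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import assembly, baseline, correlate, fcs_io, gating

log = logging.getLogger("flowmon")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """One file to drive a whole campaign analysis."""

    input_dir: Path
    output_dir: Path
    gate_file: Path | None = None
    sensor_file: Path | None = None
    rain_file: Path | None = None
    flow_rate: float = fcs_io.DEFAULT_FLOW_RATE
    duration: float = fcs_io.DEFAULT_DURATION
    dilution_factor: float = fcs_io.DEFAULT_DILUTION
    channel_aliases: dict[str, str] = field(default_factory=dict)
    exclusion_windows: list[tuple[datetime, datetime]] = field(default_factory=list)
    weekdays_only: bool = False
    detector_k: float = 3.0
    detector_m: int = 4
    correlation_window: tuple[datetime, datetime] | None = None
    correlation_parameters: list[str] = field(
        default_factory=lambda: ["tcc", "pct_lna", "T", "DO", "EC", "pH"]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detector_k <= 0 or self.detector_m < 1:
            raise ValueError("need detector_k > 0 and detector_m >= 1")
        for key in ("input_dir", "output_dir", "gate_file", "sensor_file", "rain_file"):
            v = getattr(self, key)
            if v is not None:
                setattr(self, key, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "exclusion_windows" in raw:
            raw["exclusion_windows"] = [
                (pd.Timestamp(s).to_pydatetime(), pd.Timestamp(e).to_pydatetime())
                for s, e in raw["exclusion_windows"]
            ]
        if raw.get("correlation_window"):
            s, e = raw["correlation_window"]
            raw["correlation_window"] = (
                pd.Timestamp(s).to_pydatetime(),
                pd.Timestamp(e).to_pydatetime(),
            )
        return cls(**raw)

    def load_gate(self) -> gating.GateSet:
        if self.gate_file is not None:
            if not Path(self.gate_file).exists():
                raise PipelineError(f"gate file not found: {self.gate_file}")
            return gating.GateSet.from_json(self.gate_file)
        return gating.default_gate()


def read_campaign_fcs(config: PipelineConfig) -> list[fcs_io.FcmSample]:
    """All FCS files under input_dir, sorted by filename."""
    paths = sorted(Path(config.input_dir).glob("*.fcs"))
    samples = []
    for p in paths:
        try:
            samples.append(
                fcs_io.read_fcs(
                    p,
                    aliases=config.channel_aliases or None,
                    flow_rate=config.flow_rate,
                    duration=config.duration,
                    dilution_factor=config.dilution_factor,
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate with the file
            raise PipelineError(f"stage=read sample={p.name}: {exc}") from exc
    log.info("stage=read n_samples=%d", len(samples))
    return samples


def gate_samples(
    samples: Iterable[fcs_io.FcmSample], gate: gating.GateSet
) -> list[gating.SampleSummary]:
    summaries = []
    n_in = 0
    for s in samples:
        n_in += 1
        try:
            summaries.append(gating.summarize_sample(s, gate))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=gate sample={s.sample_id}: {exc}") from exc
    assert len(summaries) == n_in, "gating must conserve sample count"
    log.info("stage=gate n_summaries=%d", len(summaries))
    return summaries


def build_series(
    summaries: Sequence[gating.SampleSummary],
    sensor_log: fcs_io.SensorLog | None = None,
    rain_log: fcs_io.RainfallLog | None = None,
    grid: pd.DatetimeIndex | None = None,
) -> assembly.MultiSeries:
    fcm = assembly.assemble_fcm_series(summaries, grid=grid)
    sensors = (
        assembly.downsample_sensors(sensor_log, fcm.frame.index)
        if sensor_log is not None
        else None
    )
    series = assembly.join_series(fcm, sensors=sensors, rain=rain_log)
    log.info(
        "stage=assemble n_slots=%d n_filled=%d",
        len(series),
        int(series.frame["tcc"].count()),
    )
    return series


@dataclass
class AnalysisResult:
    """Everything the baseline/event/correlation stages produce."""

    series: assembly.MultiSeries
    subset: assembly.MultiSeries
    stats: dict[str, tuple[float, float, int]]
    profiles: dict[str, baseline.DielProfile]
    night_drift_tcc: float
    events: list[baseline.EventWindow]
    correlation: correlate.CorrelationResult | None


def analyze_series(
    series: assembly.MultiSeries,
    exclusions: baseline.ExclusionSpec,
    detector_k: float = 3.0,
    detector_m: int = 4,
    correlation_window: tuple[datetime, datetime] | None = None,
    correlation_parameters: Sequence[str] | None = None,
) -> AnalysisResult:
    """Baseline statistics, diel profiles, events and correlations."""
    subset = baseline.apply_exclusions(series, exclusions)
    stats, profiles = {}, {}
    for p in ("tcc", "pct_lna"):
        stats[p] = baseline.baseline_stats(subset, p)
        profiles[p] = baseline.pool_diel(subset, p)
    log.info(
        "stage=baseline n_subset=%d mean_tcc=%.1f", stats["tcc"][2], stats["tcc"][0]
    )
    try:
        drift = baseline.estimate_night_drift(profiles["tcc"])
    except ValueError:
        drift = float("nan")
    events = baseline.flag_events(series, profiles["tcc"], k=detector_k, m=detector_m)
    log.info("stage=events n_events=%d", len(events))

    corr = None
    if correlation_parameters:
        frame = series.frame
        if correlation_window is not None:
            s, e = correlation_window
            frame = frame.loc[(frame.index >= pd.Timestamp(s)) & (frame.index < pd.Timestamp(e))]
        cols = [p for p in correlation_parameters if frame[p].count() >= 3]
        if len(cols) >= 2:
            corr = correlate.correlation_analysis(frame[cols])
            log.info("stage=correlate n_params=%d", len(cols))
    return AnalysisResult(
        series=series,
        subset=subset,
        stats=stats,
        profiles=profiles,
        night_drift_tcc=drift,
        events=events,
        correlation=corr,
    )


def write_results(
    result: AnalysisResult,
    summaries: Sequence[gating.SampleSummary],
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "sample_summaries.csv"
    gating.summaries_to_frame(summaries).to_csv(p, index=False)
    paths["summaries"] = p

    p = outdir / "multiseries.csv"
    result.series.to_csv(p)
    paths["multiseries"] = p

    for name, profile in result.profiles.items():
        p = outdir / f"diel_{name}.csv"
        baseline.diel_profile_frame(profile).to_csv(p, index_label="minute_of_day")
        paths[f"diel_{name}"] = p

    p = outdir / "baseline_stats.json"
    p.write_text(
        json.dumps(
            {
                k: {"mean": v[0], "sd": v[1], "n": v[2]}
                for k, v in result.stats.items()
            }
            | {"night_drift_tcc_per_h": result.night_drift_tcc},
            indent=1,
        )
    )
    paths["baseline_stats"] = p

    p = outdir / "events.json"
    p.write_text(
        json.dumps(
            [
                {
                    "parameter": e.parameter,
                    "start": str(e.start),
                    "end": str(e.end),
                    "peak_value": e.peak_value,
                    "peak_excess_sd": e.peak_excess_sd,
                    "recovery_h": e.recovery_h,
                }
                for e in result.events
            ],
            indent=1,
        )
    )
    paths["events"] = p

    if result.correlation is not None:
        corr = result.correlation
        for name, mat in (
            ("pcc", corr.pcc),
            ("scc", corr.scc),
            ("p_pcc", corr.p_pcc),
            ("p_scc", corr.p_scc),
        ):
            p = outdir / f"correlation_{name}.csv"
            mat.to_csv(p)
            paths[f"correlation_{name}"] = p
        p = outdir / "correlation_order.json"
        p.write_text(
            json.dumps(
                {
                    "leaf_order": corr.leaf_order,
                    "linkage": corr.linkage.tolist(),
                },
                indent=1,
            )
        )
        paths["correlation_order"] = p
        paths.update(
            {
                f"heatmap_{k}": v
                for k, v in correlate.export_heatmap(
                    corr, outdir / "heatmap"
                ).items()
            }
        )
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """The full file-based chain; returns the written artifact paths."""
    gate = config.load_gate()
    samples = read_campaign_fcs(config)
    if not samples:
        raise PipelineError(f"stage=read: no FCS files under {config.input_dir}")
    summaries = gate_samples(samples, gate)
    sensor_log = (
        fcs_io.read_sensor_log(config.sensor_file) if config.sensor_file else None
    )
    rain_log = fcs_io.read_rainfall_log(config.rain_file) if config.rain_file else None
    series = build_series(summaries, sensor_log, rain_log)
    result = analyze_series(
        series,
        baseline.ExclusionSpec(
            windows=config.exclusion_windows, weekdays_only=config.weekdays_only
        ),
        detector_k=config.detector_k,
        detector_m=config.detector_m,
        correlation_window=config.correlation_window,
        correlation_parameters=config.correlation_parameters,
    )
    return write_results(result, summaries, config.output_dir)
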