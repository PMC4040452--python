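"""Synthetic monitoring-campaign generator with a ground-truth ledger.

Two presets emulate the study systems:

* ``tap_published`` — 14 days of municipal drinking water: stable baseline
  around 108.3 cells/µL (57.6% LNA), a diel cycle with a slow nocturnal
  rise (0.8 cells/µL/h over 20:00–08:00), a morning maximum near
  119 cells/µL, and a sustained shift event from day 10 (mean
  145.1 cells/µL) decaying until the campaign end. %LNA couples weakly and
  negatively to TCC (measured r ≈ −0.34).
* ``river_published`` — 12 days of river water: baseline 991.3 cells/µL
  (54.9% LNA), a diel cycle with a late-morning minimum and late-afternoon
  maximum, and two rainfall events (3.1 mm/8 h on day 2, 1.4 mm/3 h on
  day 10) driving TCC spikes above 2000 and 1500 cells/µL with %LNA
  depressed below 45% and recovery within ~24 h. Electrical conductivity
  couples to TCC (measured r ≈ 0.77) and pH to %LNA (r ≈ 0.45).

Slot-level truth is baseline + zero-mean diel template + event terms +
Gaussian noise; the residual noise SD is chosen so that the total baseline
variance (diel + noise) matches the programmed overall SD, floored at a
small value when the diel template alone exhausts the budget. Couplings
are calibrated analytically on the *measured* scale: the generator
accounts for Poisson counting noise in TCC and binomial noise in %LNA at
the programmed acquisition settings, so the programmed correlation is what
the analysis pipeline should recover.

Event-level FCS samples draw a Poisson event count (expected count =
TCC × analyzed volume / dilution factor), assign cells to the LNA or HNA
population per the slot's true %LNA plus a background population, and
sample channel values from per-population log-normals. The cluster
locations/scales are invented (no channel statistics are published for
the study systems) and are documented as such; defaults place LNA below
HNA on FL1 with clear separation, and background outside the total-cell
gate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .assembly import ALL_COLUMNS, MultiSeries, make_grid
from .baseline import ExclusionSpec
from .fcs_io import (
    CHANNELS,
    DEFAULT_DILUTION,
    DEFAULT_DURATION,
    DEFAULT_FLOW_RATE,
    FcmSample,
    write_fcs,
)

SLOT_MIN = 15
SLOTS_PER_DAY = 96


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class EventSpec:
    """One programmed excursion.

    ``kind`` is "spike" (ramp, hold, exponential decay — a rainfall washout)
    or "shift" (sustained level change with linear decay to ``end_h``).
    ``peak_tcc`` is the absolute target level at full amplitude;
    ``pct_lna_floor`` (spikes) is the %LNA value at full depression.
    """

    kind: str
    start_h: float
    peak_tcc: float
    ramp_h: float = 4.0
    hold_h: float = 4.0
    decay_tau_h: float = 5.0
    end_h: float | None = None  # shifts: linear decay endpoint
    end_amplitude: float | None = None  # shifts: residual amplitude at end_h
    pct_lna_floor: float | None = None
    rain_mm: float = 0.0
    rain_start_h: float | None = None
    rain_duration_h: float = 0.0


@dataclass
class PopulationParams:
    """Per-channel log10 location/scale of one event population."""

    loc: dict[str, float]
    scale: dict[str, float]


def _default_clusters() -> dict[str, PopulationParams]:
    # Invented channel statistics (none are published for these systems):
    # LNA below HNA on FL1 with ~3.75 sigma separation from the 4.0 split,
    # background below the gate's lower FL3 edge.
    return {
        "lna": PopulationParams(
            loc={"FL1-H": 3.55, "FL3-H": 2.7, "FSC-H": 3.2, "SSC-H": 3.0},
            scale={"FL1-H": 0.12, "FL3-H": 0.25, "FSC-H": 0.3, "SSC-H": 0.3},
        ),
        "hna": PopulationParams(
            loc={"FL1-H": 4.45, "FL3-H": 3.0, "FSC-H": 3.6, "SSC-H": 3.4},
            scale={"FL1-H": 0.12, "FL3-H": 0.25, "FSC-H": 0.3, "SSC-H": 0.3},
        ),
        "background": PopulationParams(
            loc={"FL1-H": 3.1, "FL3-H": 0.3, "FSC-H": 2.5, "SSC-H": 2.3},
            scale={"FL1-H": 0.15, "FL3-H": 0.2, "FSC-H": 0.4, "SSC-H": 0.4},
        ),
    }


@dataclass
class SensorChannelSpec:
    """An independently generated sensor channel: diel sinusoid + noise."""

    mean: float
    amplitude: float
    peak_hour: float
    noise_sd: float
    fine_noise_sd: float = 0.0  # extra jitter on the emitted 10-s records


@dataclass
class CampaignConfig:
    """Everything that defines one synthetic campaign."""

    site: str
    start: datetime
    duration_days: int
    seed: int = 0
    cadence_min: int = SLOT_MIN
    # FCM truth process
    baseline_tcc: float = 100.0  # cells/µL
    baseline_sd: float = 8.0  # total baseline SD (diel + residual noise)
    baseline_pct_lna: float = 55.0  # %
    pct_lna_sd: float = 2.0  # total measured %LNA SD
    diel_template: Sequence[tuple[float, float]] = ()  # (hour, rel cells/µL)
    night_drift: float = 0.0  # cells/µL/h encoded by the tap template
    lna_tcc_coupling: float = 0.0  # target measured corr(TCC, %LNA)
    noise_floor_sd: float = 1.5  # cells/µL
    events: Sequence[EventSpec] = ()
    # sensors (None => no sensor log, e.g. the tap campaign)
    sensors: dict[str, SensorChannelSpec] | None = None
    ec_sd: float = 25.0  # µS/cm, total
    ec_tcc_coupling: float | None = None
    ph_sd: float = 0.15
    ph_lna_coupling: float | None = None
    missingness: float = 0.03
    # acquisition
    flow_rate: float = DEFAULT_FLOW_RATE
    duration_s: float = DEFAULT_DURATION
    dilution_factor: float = DEFAULT_DILUTION
    background_fraction: float = 0.2
    clusters: dict[str, PopulationParams] = field(default_factory=_default_clusters)

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.pct_lna_sd < 0:
            raise ConfigError("spreads must be nonnegative")
        if not 0 < self.baseline_pct_lna < 100:
            raise ConfigError("baseline_pct_lna must be in (0, 100)")
        for c in (self.lna_tcc_coupling, self.ec_tcc_coupling, self.ph_lna_coupling):
            if c is not None and not -1 < c < 1:
                raise ConfigError("couplings must lie strictly inside (-1, 1)")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness must be in [0, 1)")
        end_h = self.duration_days * 24
        for ev in self.events:
            if not 0 <= ev.start_h < end_h:
                raise ConfigError("event outside the campaign window")

    @property
    def analyzed_volume(self) -> float:
        return self.flow_rate * self.duration_s / 60.0

    @property
    def expected_cells_per_sample(self) -> float:
        return self.baseline_tcc * self.analyzed_volume / self.dilution_factor


@dataclass
class GroundTruth:
    """Slot-level truth and per-sample population counts."""

    slots: pd.DataFrame  # indexed by slot timestamp
    samples: pd.DataFrame  # one row per emitted FCS sample
    programmed: dict  # the headline programmed values, for recovery checks


# ---------------------------------------------------------------------------
# diel templates


def tap_diel_template(
    night_slope: float = 0.8, morning_excess: float = 10.7
) -> list[tuple[float, float]]:
    """Piecewise-linear tap-water diel shape (relative cells/µL).

    Encodes: a linear nocturnal rise at ``night_slope`` cells/µL/h across
    20:00-08:00, a morning plateau of ``morning_excess`` above the daily
    mean over 08:00-10:00, a sharp late-morning drop, a noon bump, and an
    afternoon minimum near 15:00. The daytime trough depth is solved so
    the continuous-time daily mean is ~0.
    """
    a = morning_excess - 12.0 * night_slope  # value at 20:00
    # trough level solving the zero-daily-mean trapezoid balance:
    # 8.5 a + 9 M + 6.5 c - 5 = 0
    c = (5.0 - 8.5 * a - 9.0 * morning_excess) / 6.5
    return [
        (0.0, a + 4 * night_slope),
        (8.0, morning_excess),
        (10.0, morning_excess),
        (12.0, c),
        (13.0, c + 6.0),
        (14.0, c - 2.0),
        (15.0, c - 3.0),
        (20.0, a),
        (24.0, a + 4 * night_slope),
    ]


def river_diel_template() -> list[tuple[float, float]]:
    """River diel shape: late-morning minimum, late-afternoon maximum."""
    return [
        (0.0, 10.0),
        (7.0, -60.0),
        (9.5, -140.0),
        (12.5, -140.0),
        (14.5, -30.0),
        (16.0, 75.0),
        (18.0, 75.0),
        (21.0, 30.0),
        (24.0, 10.0),
    ]


def _eval_template(
    template: Sequence[tuple[float, float]], hours_of_day: np.ndarray
) -> np.ndarray:
    if not len(template):
        return np.zeros_like(hours_of_day, dtype=float)
    pts = np.asarray(template, dtype=float)
    vals = np.interp(hours_of_day, pts[:, 0], pts[:, 1])
    # recenter to zero mean over the 96 bin starts so the programmed
    # baseline level is exactly the subset mean in expectation
    bin_hours = np.arange(SLOTS_PER_DAY) * (SLOT_MIN / 60.0)
    vals -= np.interp(bin_hours, pts[:, 0], pts[:, 1]).mean()
    return vals


# ---------------------------------------------------------------------------
# coupling calibration


def _calibrate_coupling(
    rho: float,
    sigma_y_meas: float,
    sigma_x_latent: float,
    sigma_x_meas: float,
    sigma_y_noise: float = 0.0,
) -> tuple[float, float]:
    """Gain and residual SD so the MEASURED correlation equals ``rho``.

    Y = g·z_X + ε with z_X the standardized latent of X; X and Y are
    observed with independent measurement noise. Solves
    rho = g·σ_X,lat / (σ_Y,meas·σ_X,meas) with total Var(Y_meas) fixed.
    """
    g = rho * sigma_y_meas * sigma_x_meas / sigma_x_latent
    eps_var = sigma_y_meas**2 - g**2 - sigma_y_noise**2
    if eps_var <= 0:
        raise ConfigError(
            f"coupling {rho} infeasible: gain {g:.3g} exhausts the variance "
            f"budget {sigma_y_meas}^2 given measurement noise {sigma_y_noise:.3g}"
        )
    return g, float(np.sqrt(eps_var))


def _event_shape(cfg: EventSpec, hours: np.ndarray) -> np.ndarray:
    """Normalized (max 1) temporal shape of an event at absolute hours."""
    t = hours - cfg.start_h
    s = np.zeros_like(t)
    if cfg.kind == "shift":
        end_h = cfg.end_h if cfg.end_h is not None else cfg.start_h + 96.0
        frac = cfg.end_amplitude if cfg.end_amplitude is not None else 0.3
        span = max(end_h - cfg.start_h, 1e-9)
        inside = (t >= 0) & (hours < end_h)
        s[inside] = 1.0 + (frac - 1.0) * (t[inside] / span)
        return s
    up = (t >= 0) & (t < cfg.ramp_h)
    s[up] = t[up] / max(cfg.ramp_h, 1e-9)
    hold = (t >= cfg.ramp_h) & (t < cfg.ramp_h + cfg.hold_h)
    s[hold] = 1.0
    down = t >= cfg.ramp_h + cfg.hold_h
    s[down] = np.exp(-(t[down] - cfg.ramp_h - cfg.hold_h) / max(cfg.decay_tau_h, 1e-9))
    return s


# ---------------------------------------------------------------------------
# campaign simulation


def simulate_campaign(config: CampaignConfig) -> tuple[MultiSeries, GroundTruth]:
    """Slot-level truth for a whole campaign (deterministic per seed)."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    grid = make_grid(
        config.start, config.start + timedelta(days=config.duration_days)
    )
    n = len(grid)
    hours = ((grid - grid[0]) / pd.Timedelta(hours=1)).to_numpy()
    hod = (grid.hour + grid.minute / 60.0).to_numpy()

    diel = _eval_template(config.diel_template, hod)
    diel_var = float(np.var(diel))
    resid_sd = float(
        np.sqrt(max(config.baseline_sd**2 - diel_var, config.noise_floor_sd**2))
    )
    tcc_noise = rngs[0].normal(0.0, resid_sd, n)
    tcc_baseline_latent = config.baseline_tcc + diel + tcc_noise
    sigma_tcc_latent = float(np.sqrt(diel_var + resid_sd**2))

    event_term = np.zeros(n)
    event_id = np.full(n, -1)
    pct_depression = np.zeros(n)
    for i, ev in enumerate(config.events):
        shape = _event_shape(ev, hours)
        amp = ev.peak_tcc - config.baseline_tcc
        event_term += amp * shape
        event_id[shape > 0.05] = i
        if ev.pct_lna_floor is not None:
            pct_depression = np.maximum(
                pct_depression, (config.baseline_pct_lna - ev.pct_lna_floor) * shape
            )
    tcc_true = np.maximum(tcc_baseline_latent + event_term, 1.0)

    # measurement-noise scales implied by the acquisition settings
    n_expected = config.expected_cells_per_sample
    conc_per_count = config.dilution_factor / config.analyzed_volume
    sigma_tcc_meas = float(
        np.sqrt(sigma_tcc_latent**2 + n_expected * conc_per_count**2)
    )
    p0 = config.baseline_pct_lna
    sigma_pct_binom = float(np.sqrt(p0 * (100.0 - p0) / n_expected))

    z_tcc = (tcc_baseline_latent - config.baseline_tcc) / sigma_tcc_latent
    beta, pct_eps_sd = _calibrate_coupling(
        config.lna_tcc_coupling,
        config.pct_lna_sd,
        sigma_tcc_latent,
        sigma_tcc_meas,
        sigma_y_noise=sigma_pct_binom,
    ) if config.lna_tcc_coupling else (0.0, config.pct_lna_sd)
    pct_latent = p0 + beta * z_tcc + rngs[1].normal(0.0, pct_eps_sd, n)
    sigma_pct_latent = float(np.sqrt(beta**2 + pct_eps_sd**2))
    pct_true = np.clip(pct_latent - pct_depression, 1.0, 99.0)

    frame = pd.DataFrame(index=grid, columns=list(ALL_COLUMNS), dtype=float)
    frame["tcc"] = tcc_true
    frame["pct_lna"] = pct_true
    frame["rain"] = 0.0

    sensor_latents = {}
    if config.sensors is not None:
        for ch in ("T", "DO"):
            spec = config.sensors[ch]
            vals = (
                spec.mean
                + spec.amplitude * np.cos(2 * np.pi * (hod - spec.peak_hour) / 24.0)
                + rngs[2].normal(0.0, spec.noise_sd, n)
            )
            frame[ch] = vals
            sensor_latents[ch] = vals
        z_full = (tcc_true - config.baseline_tcc) / sigma_tcc_latent
        if config.ec_tcc_coupling is not None:
            g_ec, ec_eps = _calibrate_coupling(
                config.ec_tcc_coupling, config.ec_sd, sigma_tcc_latent, sigma_tcc_meas
            )
            ec = config.sensors["EC"].mean + g_ec * z_full + rngs[3].normal(0.0, ec_eps, n)
        else:
            spec = config.sensors["EC"]
            ec = spec.mean + rngs[3].normal(0.0, spec.noise_sd, n)
        frame["EC"] = ec
        sensor_latents["EC"] = ec
        sigma_pct_meas = float(np.sqrt(sigma_pct_latent**2 + sigma_pct_binom**2))
        if config.ph_lna_coupling is not None:
            z_lna = (pct_latent - p0) / sigma_pct_latent
            g_ph, ph_eps = _calibrate_coupling(
                config.ph_lna_coupling, config.ph_sd, sigma_pct_latent, sigma_pct_meas
            )
            ph = config.sensors["pH"].mean + g_ph * z_lna + rngs[4].normal(0.0, ph_eps, n)
        else:
            spec = config.sensors["pH"]
            ph = spec.mean + rngs[4].normal(0.0, spec.noise_sd, n)
        frame["pH"] = ph
        sensor_latents["pH"] = ph

    for ev in config.events:
        if ev.rain_mm > 0 and ev.rain_start_h is not None:
            in_win = (hours >= ev.rain_start_h) & (
                hours < ev.rain_start_h + ev.rain_duration_h
            )
            k = int(in_win.sum())
            if k:
                frame.loc[in_win, "rain"] += ev.rain_mm / k

    missing = rngs[5].random(n) < config.missingness

    slots = pd.DataFrame(index=grid)
    slots["tcc_true"] = tcc_true
    slots["pct_lna_true"] = pct_true
    slots["event_id"] = event_id
    slots["missing"] = missing
    slots["z_tcc"] = z_tcc
    for ch, vals in sensor_latents.items():
        slots[f"{ch}_latent"] = vals

    programmed = {
        "baseline_tcc": config.baseline_tcc,
        "baseline_sd": config.baseline_sd,
        "baseline_pct_lna": config.baseline_pct_lna,
        "pct_lna_sd": config.pct_lna_sd,
        "night_drift": config.night_drift,
        "lna_tcc_coupling": config.lna_tcc_coupling,
        "ec_tcc_coupling": config.ec_tcc_coupling,
        "ph_lna_coupling": config.ph_lna_coupling,
        "sigma_tcc_latent": sigma_tcc_latent,
        "resid_sd": resid_sd,
        "n_slots": n,
        "n_missing": int(missing.sum()),
        "events": [dataclasses.asdict(ev) for ev in config.events],
    }
    truth = MultiSeries(
        frame=frame,
        meta={"site": config.site, "start": grid[0], "end": grid[-1] + pd.Timedelta(minutes=15), "synthetic": True},
    )
    gt = GroundTruth(slots=slots, samples=pd.DataFrame(), programmed=programmed)
    return truth, gt


def simulate_fcm_events(
    true_tcc: float,
    true_pct_lna: float,
    config: CampaignConfig,
    rng: np.random.Generator,
    timestamp: datetime,
    sample_id: str,
) -> tuple[FcmSample, dict]:
    """One acquisition: Poisson cell count, population assignment, channels."""
    lam_cells = true_tcc * config.analyzed_volume / config.dilution_factor
    n_cells = int(rng.poisson(lam_cells))
    n_lna = int(rng.binomial(n_cells, true_pct_lna / 100.0)) if n_cells else 0
    n_hna = n_cells - n_lna
    n_bg = int(rng.poisson(lam_cells * config.background_fraction))

    blocks = []
    for name, count in (("lna", n_lna), ("hna", n_hna), ("background", n_bg)):
        pop = config.clusters[name]
        cols = {
            ch: 10.0 ** rng.normal(pop.loc[ch], pop.scale[ch], count)
            for ch in CHANNELS
        }
        blocks.append(pd.DataFrame(cols))
    events = pd.concat(blocks, ignore_index=True)
    events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)

    sample = FcmSample(
        sample_id=sample_id,
        timestamp=timestamp,
        events=events,
        flow_rate=config.flow_rate,
        duration=config.duration_s,
        dilution_factor=config.dilution_factor,
    )
    truth = {
        "sample_id": sample_id,
        "timestamp": timestamp,
        "n_lna_true": n_lna,
        "n_hna_true": n_hna,
        "n_background_true": n_bg,
    }
    return sample, truth


def generate_samples(
    truth: MultiSeries, gt: GroundTruth, config: CampaignConfig
) -> Iterable[FcmSample]:
    """Yield one FcmSample per non-missing slot; records truth counts in gt."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rows = []
    for i, (ts, slot) in enumerate(gt.slots.iterrows()):
        if slot["missing"]:
            continue
        sid = f"{config.site}_{ts.strftime('%Y%m%d-%H%M')}"
        sample, srow = simulate_fcm_events(
            slot["tcc_true"], slot["pct_lna_true"], config, rng, ts.to_pydatetime(), sid
        )
        rows.append(srow)
        yield sample
    gt.samples = pd.DataFrame(rows)


def emit_campaign_files(
    truth: MultiSeries,
    gt: GroundTruth,
    config: CampaignConfig,
    outdir: str | Path,
    sensor_cadence_s: float = 10.0,
    rain_cadence_min: int = 10,
) -> dict[str, Path]:
    """Write the full campaign file tree: FCS files, sensor/rain CSVs, ledger."""
    outdir = Path(outdir)
    fcs_dir = outdir / "fcs"
    fcs_dir.mkdir(parents=True, exist_ok=True)
    for sample in generate_samples(truth, gt, config):
        write_fcs(sample, fcs_dir / f"{sample.sample_id}.fcs")

    paths: dict[str, Path] = {"fcs_dir": fcs_dir}
    if config.sensors is not None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        per_slot = int(round(SLOT_MIN * 60 / sensor_cadence_s))
        rows = []
        for ts, slot in gt.slots.iterrows():
            base = pd.Timestamp(ts)
            for j in range(per_slot):
                rows.append(
                    {
                        "timestamp": base + pd.Timedelta(seconds=j * sensor_cadence_s),
                        **{
                            ch: slot[f"{ch}_latent"]
                            + rng.normal(0.0, config.sensors[ch].fine_noise_sd)
                            for ch in ("T", "DO", "EC", "pH")
                        },
                    }
                )
        sensors_csv = outdir / "sensors.csv"
        pd.DataFrame(rows).to_csv(sensors_csv, index=False)
        paths["sensors"] = sensors_csv

    rain_rows = []
    per_slot = SLOT_MIN // rain_cadence_min
    for ts, slot in truth.frame.iterrows():
        for j in range(per_slot):
            rain_rows.append(
                {
                    "timestamp": pd.Timestamp(ts) + pd.Timedelta(minutes=j * rain_cadence_min),
                    "rain": slot["rain"] / per_slot,
                }
            )
    rain_csv = outdir / "rain.csv"
    pd.DataFrame(rain_rows).to_csv(rain_csv, index=False)
    paths["rain"] = rain_csv

    ledger_csv = outdir / "ground_truth_slots.csv"
    gt.slots.to_csv(ledger_csv, index_label="timestamp")
    paths["ledger_slots"] = ledger_csv
    samples_csv = outdir / "ground_truth_samples.csv"
    gt.samples.to_csv(samples_csv, index=False)
    paths["ledger_samples"] = samples_csv
    ledger_json = outdir / "ground_truth.json"
    ledger_json.write_text(json.dumps(gt.programmed, indent=1, default=str))
    paths["ledger"] = ledger_json
    config_yaml = outdir / "config.yaml"
    config_yaml.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))
    paths["config"] = config_yaml
    return paths


def _config_to_dict(config: CampaignConfig) -> dict:
    d = dataclasses.asdict(config)
    d["start"] = config.start.isoformat()
    return d


# ---------------------------------------------------------------------------
# presets


def tap_published(seed: int = 0) -> CampaignConfig:
    """14-day drinking-water campaign at the published statistics."""
    start = datetime(2013, 8, 12)  # a Monday: weekday/weekend structure matters
    return CampaignConfig(
        site="tap",
        start=start,
        duration_days=14,
        seed=seed,
        baseline_tcc=108.3,
        baseline_sd=7.8,
        baseline_pct_lna=57.6,
        pct_lna_sd=2.0,
        diel_template=tap_diel_template(night_slope=0.8, morning_excess=10.7),
        night_drift=0.8,
        lna_tcc_coupling=-0.34,
        events=[
            EventSpec(
                kind="shift",
                start_h=9 * 24.0,  # day 10, lasting to the campaign end
                peak_tcc=108.3 + 55.0,  # decaying shift averaging ~145.1 cells/µL
                end_h=14 * 24.0,
                end_amplitude=18.6 / 55.0,
            )
        ],
        sensors=None,
        missingness=0.03,
    )


def river_published(seed: int = 0) -> CampaignConfig:
    """12-day river campaign with two rainfall events, at the published stats."""
    start = datetime(2013, 6, 12)  # a Wednesday: days 6-9 fall Mon-Thu
    return CampaignConfig(
        site="river",
        start=start,
        duration_days=12,
        seed=seed,
        baseline_tcc=991.3,
        baseline_sd=98.2,
        baseline_pct_lna=54.9,
        pct_lna_sd=1.6,
        diel_template=river_diel_template(),
        lna_tcc_coupling=0.5,
        events=[
            EventSpec(
                kind="spike",
                start_h=24.0 + 6.0,  # day 2, following the rain onset
                peak_tcc=2500.0,
                ramp_h=6.0,
                hold_h=4.0,
                decay_tau_h=5.0,
                pct_lna_floor=42.0,
                rain_mm=3.1,
                rain_start_h=24.0 + 4.0,
                rain_duration_h=8.0,
            ),
            EventSpec(
                kind="spike",
                start_h=9 * 24.0 + 11.0,  # day 10
                peak_tcc=1800.0,
                ramp_h=4.0,
                hold_h=2.0,
                decay_tau_h=4.0,
                pct_lna_floor=43.0,
                rain_mm=1.4,
                rain_start_h=9 * 24.0 + 10.0,
                rain_duration_h=3.0,
            ),
        ],
        sensors={
            "T": SensorChannelSpec(15.0, 2.5, 14.0, 0.15, 0.05),
            "DO": SensorChannelSpec(9.5, 1.2, 14.5, 0.10, 0.03),
            "EC": SensorChannelSpec(480.0, 0.0, 0.0, 25.0, 1.0),
            "pH": SensorChannelSpec(8.1, 0.0, 0.0, 0.15, 0.01),
        },
        ec_sd=25.0,
        ec_tcc_coupling=0.77,
        ph_sd=0.15,
        ph_lna_coupling=0.45,
        missingness=0.04,
    )


PRESETS = {"tap_published": tap_published, "river_published": river_published}


def preset_exclusions(config: CampaignConfig) -> ExclusionSpec:
    """The curated baseline exclusions matching each preset's events."""
    start = config.start
    if config.site == "tap":
        return ExclusionSpec(
            windows=[(start + timedelta(days=9), start + timedelta(days=14))],
            weekdays_only=True,
        )
    return ExclusionSpec(
        windows=[
            (start, start + timedelta(days=3)),
            (start + timedelta(days=9), start + timedelta(days=12)),
        ],
        weekdays_only=False,
    )


def dry_subset_window(config: CampaignConfig) -> tuple[datetime, datetime]:
    """The 4 consecutive dry weekdays used for the correlation analysis."""
    return (
        config.start + timedelta(days=5),
        config.start + timedelta(days=9),
    )
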