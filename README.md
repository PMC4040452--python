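# flowmon

Analysis pipeline for **automated online flow cytometry** (FCM) of aquatic
ecosystems. An online FCM system stains a water sample 1:1 with SYBR
Green I every 15 minutes and acquires it on a cytometer (66 µL/min for
30 s, FL1-H trigger at 1000). Over days to weeks this yields >1000
measurements per campaign — enough to establish a microbiological
baseline, resolve diel (24-h) patterns, and catch events such as
rainfall-driven contamination that grab sampling would miss. `flowmon`
turns the raw per-sample event files into those results:

- **Gating** — log10-transformed events are classified by a polygonal
  total-cell gate in (FL1-H, FL3-H); gated cells split at a fixed FL1
  threshold into low/high nucleic-acid content populations. Per sample:
  TCC = n_gated / (flow·t/60) × dilution (cells/µL of unstained water)
  and %LNA = 100·n_LNA/n_gated, the one-number cytometric fingerprint.
- **Assembly** — FCM summaries, 10-s sensor logs (T, DO, EC, pH; window
  means) and rainfall (window sums) joined on a strict 15-min grid.
- **Baselines** — exclusion windows + optional weekday filter; mean ± SD;
  96-bin diel profiles (mean, SE = SD/√n, n per wall-clock bin); night
  drift as the OLS slope of bin means over a midnight-wrapped window.
- **Events** — sustained excursions beyond k·SD (default 3) around the
  diel expectation for ≥ m slots (default 4), with peak, excess in SDs
  and recovery time.
- **Correlations** — z-scored, pairwise-complete Pearson/Spearman
  matrices with t-based p-values, Ward-clustered (d = 1 − r) heat-map
  ordering.
- **Synthetic campaigns** — a ground-truthed generator with presets for a
  14-day drinking-water campaign (stable ~10⁵ cells/mL baseline, diel
  cycle, multi-day shift event) and a 12-day river campaign (~10⁶
  cells/mL, two rainfall events with TCC spikes and %LNA drops, EC
  coupled to TCC), used throughout the tests as recovery oracles.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Generate a synthetic river campaign, gate it and extract the baseline:

```python
from flowmon import synthetic_data as syn
from flowmon import baseline, gating, pipeline

cfg = syn.river_published(seed=1)               # 12 d, two rain events
truth, gt = syn.simulate_campaign(cfg)          # slot-level ground truth
samples = syn.generate_samples(truth, gt, cfg)  # one FcmSample per slot
summaries = pipeline.gate_samples(samples, gating.default_gate())
series = pipeline.build_series(summaries, grid=truth.frame.index)

subset = baseline.apply_exclusions(series, syn.preset_exclusions(cfg))
mean, sd, n = baseline.baseline_stats(subset, "tcc")
print(f"baseline TCC {mean:.1f} +/- {sd:.1f} cells/uL (n={n})")

profile = baseline.pool_diel(subset, "tcc")
events = baseline.flag_events(series, profile, k=3, m=4)
for ev in sorted(events, key=lambda e: e.start):
    print(f"event {ev.start} -> {ev.end}: peak {ev.peak_value:.0f} cells/uL")
```

prints

```
baseline TCC 989.8 +/- 99.8 cells/uL (n=555)
event 2013-06-13 07:00:00 -> 2013-06-13 22:45:00: peak 2762 cells/uL
event 2013-06-21 12:30:00 -> 2013-06-21 21:30:00: peak 1982 cells/uL
```

i.e. the non-event baseline sits at ~990 cells/µL and the detector finds
exactly the two programmed rainfall events, with day-2 TCC peaking above
2000 cells/µL. During both events %LNA in `series.frame` drops below 45%
— storm runoff loads the river with high-nucleic-acid bacteria.

## Analysis scripts

The campaign study is reproduced by numbered drivers (each a thin wrapper
over the library) writing tables under `results/`:

```sh
python analysis/01_simulate_campaigns.py   # FCS trees + logs -> scratch/
python analysis/02_gate_samples.py         # per-sample summaries
python analysis/03_assemble_series.py      # 15-min joined series
python analysis/04_baselines_and_events.py # baselines, diel, drift, events
python analysis/05_correlations.py         # PCC/SCC + Ward heat map
```

There is also a `flowmon` CLI (`simulate`, `gate`, `run`) driven by a YAML
pipeline config; `flowmon run` executes the whole chain on a directory of
FCS files.

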