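# Methods

## Problem and scope

Automated online flow cytometry (FCM) measures a water source every 15
minutes: each sample is mixed 1:1 with SYBR Green I dye, incubated, and
acquired on a cytometer at 66 µL/min for 30 s with a lower FL1-H trigger
threshold of 1000. `flowmon` implements the downstream analysis train for
such campaigns: per-sample gating into total cell concentration (TCC) and
the %LNA fingerprint, assembly onto a 15-min grid together with abiotic
sensor channels (T, DO, EC, pH at 10-s cadence) and rainfall, extraction
of diel (24-h) baseline patterns, detection of events as deviations from
baseline, and standardized pairwise correlation analysis. A synthetic
campaign generator provides complete, ground-truthed campaigns for two
reference systems — a drinking-water tap and a small river — because no
raw campaign data of this kind are publicly deposited.

## Gating model

Events are log10-transformed per channel with a floor at 1 (so a raw value
of 0 maps to 0, and the transform is monotone everywhere). Stained cells
are separated from background by a fixed polygon in the (log10 FL1-H,
log10 FL3-H) plane; gated cells are split at a transformed FL1-H threshold
into low (LNA, below) and high (HNA, at/above) nucleic-acid-content
populations. Published work on SYBR-Green drinking-water cytometry fixes
this geometry per campaign, so gates are **data**: a JSON file with the
transform name, vertex list and threshold. The packaged default is a
trapezoid spanning log10 FL1 ∈ [3.0, 6.5] × log10 FL3 ∈ [1.0, 5.5] with
the LNA/HNA split at 4.0 (i.e. FL1 = 10⁴); these coordinates are a
documented stand-in for the unpublished campaign gates, adequate for the
synthetic populations and replaceable per deployment.

Tie-breaks are fixed once: points on the polygon boundary are inside;
events exactly at the LNA/HNA threshold are HNA. Membership is computed by
a vectorized even-odd crossing-number test with explicit on-edge
detection; tests verify it against an independent pointwise ray-casting
oracle and against `shapely.covers`.

Concentrations: analyzed volume = flow rate × duration / 60 = 33 µL at the
default settings; TCC = n_gated / volume × dilution factor. The dilution
factor defaults to 2 so reported TCC refers to the unstained water (it is
not documented whether published values include this correction; the
factor is configurable). Samples with fewer than 50 gated events carry a
`low_events` QC flag — the binomial standard error of %LNA exceeds ~3.5
percentage points below that count.

## Assembly

The master grid is regular at 15 min; gaps are missing values, never
irregular spacing. FCM summaries snap to the nearest slot (ties go to the
earlier slot; duplicates keep the earliest sample and warn). Sensor
channels are reduced to the mean of valid records per left-closed window
[t, t+15 min) — the aggregation statistic for the 10-s data is not
standardized anywhere, and the window mean suppresses sensor noise;
first-value sampling is available via configuration. Rainfall is a flux
and is summed per window, which conserves total rainfall exactly.
Physically impossible sensor rows (pH outside [0, 14], negative DO/EC)
are flagged invalid and excluded from window means but never silently
dropped from the log.

## Baselines, diel profiles, events

A campaign baseline is the series outside explicitly configured exclusion
windows (event periods chosen by inspection, and optionally weekends for
weekly-patterned systems), summarized as mean ± sample SD (n−1
denominator throughout). The diel profile pools all baseline values into
96 wall-clock bins; per bin it reports mean, SE = SD/√n (undefined below
n = 2) and n. The nocturnal drift rate is the OLS slope of bin means
against bin mid-times over a clock window (default 20:00–08:00), unwrapped
across midnight.

The event detector is deliberately separate from the curated exclusions:
a slot is anomalous when |value − diel-bin mean| exceeds k × overall
baseline SD (defaults k = 3, m = 4). Runs of ≥ m anomalous slots become
events; single missing slots inside a run are bridged, and runs separated
by fewer than m in-band slots are merged, because the detector cannot
resolve two excursions closer than its own minimum duration — without the
merge, one noisy slot near the threshold during an event's decay tail
splits a single physical excursion in two. Slowly decaying shifts (such
as the tap campaign's day-10 event) can still fragment once their
amplitude hovers at the threshold for longer than m slots; that is
inherent to a fixed-band detector. Recovery time runs from the end of the
last anomalous slot to the first observed in-band slot.

## Correlation analysis

Parameters are z-scored over the analysis subset (correlation itself is
scale-invariant; standardization is kept for fidelity to the standard
workflow and for the heat-map color scale). Pearson r and Spearman ρ
(mid-ranks for ties) are computed on pairwise-complete observations —
listwise deletion would discard FCM-complete slots whenever one sensor
window is empty — with two-sided p-values from t = r√((n−2)/(1−r²)) on
n−2 df. Pairs with fewer than 3 complete observations stay missing, with
the pairwise n recorded. No multiple-testing correction is applied by
default (raw pairwise significance at the 95% level); a Holm adjustment
is available. For display, parameters are reordered by agglomerative Ward
clustering on d = 1 − r (the common heat-map practice; d is not Euclidean,
so this is an approximation, and tests pin the merge sequence to an
exhaustive Lance–Williams oracle). Leaf order is deterministic: the
smaller-height subtree first, alphabetical on the first leaf as
tie-break.

## Synthetic campaign generator

The generator defines the study conditions; its presets are programmed to
the published campaign statistics and are not tuning knobs.

**Slot-level truth.** True TCC = baseline level + zero-mean diel template
+ event terms + Gaussian noise. The diel template is piecewise linear
over the clock and recentered to zero mean over the 96 bin starts, so the
programmed baseline level is exactly the expected subset mean. The
residual noise SD is √max(SD_total² − Var(diel), floor²) with a 1.5
cells/µL floor: the programmed overall SD budgets for both the diel cycle
and slot noise.

*Tap template.* Three published constraints pin the shape: a linear
nocturnal rise of 0.8 cells/µL/h across 20:00–08:00, a 08:00–10:00
plateau 10.7 cells/µL above the daily mean (119.0 vs 108.3), and a zero
daily mean. Jointly they force a daytime trough (solved in closed form
from the trapezoid areas) deep enough that the diel SD alone is ~9
cells/µL, slightly above the published overall ±7.8; the noise floor then
applies and the realized overall SD is ≈9.5 cells/µL. The pinned means,
slope and window levels are honored exactly; the small SD excess is a
consequence of the published constraints themselves.

*River template.* Late-morning minimum (09:30–12:30 ≈ 850–880 cells/µL
around the 991.3 baseline) and late-afternoon maximum (16:00–18:00), with
amplitudes giving a diel SD of ~75 cells/µL and residual noise of ~63
cells/µL to meet the overall ±98.2.

**Events.** Spikes (rainfall washout) ramp linearly to an absolute peak
level, hold, and decay exponentially (river day 2: peak 2500 cells/µL,
6 h ramp, 4 h hold, τ = 5 h, with 3.1 mm of rain over 8 h; day 10: peak
1800, 1.4 mm over 3 h), giving recovery within ~24 h. During spikes %LNA
is depressed toward a floor (42 and 43%) with the same temporal shape.
The tap day-10 event is a sustained shift: +55 cells/µL decaying linearly
to +18.6 at the campaign end, averaging the published 145.1 cells/µL over
the event window; tap %LNA is unaffected by the shift.

**Couplings on the measured scale.** The published correlations are
properties of *measured* series, so the generator calibrates analytically
for measurement noise: TCC carries Poisson counting noise (SD
√(TCC·dilution/volume) ≈ 2.6 cells/µL tap, 7.7 river) and %LNA carries
binomial noise at the expected gated count (≈1.2 points tap, 0.39
river). For a coupling Y = g·z_X + ε with target measured correlation ρ,
g = ρ·σ_Y,meas·σ_X,meas/σ_X,lat and Var(ε) makes the total variance
budget close; infeasible budgets raise a configuration error. This yields
tap TCC–%LNA ≈ −0.34, river EC–TCC ≈ 0.77 and pH–%LNA ≈ 0.45 as
*recovered* by the pipeline, not merely as latent parameters. River %LNA
couples positively to TCC (+0.5) in dry weather, matching the opposite
tendencies of the two systems. T and DO are independent diel sinusoids
(peaks near 14:00–14:30) with slot noise; EC and pH inherit their diel
structure through the couplings.

**Event-level samples.** Per non-missing slot, the cell count is
Poisson(TCC × 33 µL / 2); cells are LNA with probability %LNA/100;
a background population (20% of the cell rate) sits below the gate's FL3
edge. Channel values are per-population log-normals: LNA at log10 FL1
3.55 ± 0.12, HNA at 4.45 ± 0.12 (≈3.75 σ from the 4.0 split, ~10⁻⁴
misclassification), background FL3 at 0.3 ± 0.2. **These cluster
parameters are invented** — no per-channel statistics are published for
the study systems — and only their separation properties matter for the
recovery tests.

**Calendars.** The tap campaign starts on a Monday (2013-08-12) so the
weekday/weekend structure and the day-10–14 event reproduce a ~650-slot
weekday baseline; the river campaign starts on a Wednesday (2013-06-12)
so the dry-weather correlation window (days 6–9) falls Monday–Thursday.
Missingness is i.i.d. per slot: 3% (tap) and 4% (river), matching the
reported sample counts (1302/1344 and 1104/1152). All draws come from
per-purpose child generators of one seed; identical config + seed gives
byte-identical ledgers.

**What the generator does not emulate.** Instrument drift and fouling,
autocorrelated sensor noise, turbidity interference during rain events,
weekend-specific sensor patterns, non-Poisson overdispersion of counts,
and any mechanistic hydrology or growth/detachment dynamics. Passing
recovery tests therefore demonstrates that the analysis train is
self-consistent and unbiased under the programmed conditions — not that
it is robust to every artifact of real deployments.

## Numerical choices and degenerate inputs

- log10 transform floors at 1; zero-event samples yield TCC 0 and
  undefined %LNA with a QC flag.
- Polygon gates must be simple with ≥3 vertices and nonzero area; the
  LNA/HNA threshold must lie within the polygon's FL1 extent.
- Standardization refuses zero-variance parameters by name; correlations
  need ≥3 complete pairs.
- Sample SD uses n−1 everywhere; SE is undefined below n = 2.
- Problem sizes: the full-scale recovery runs simulate every event of
  every sample (≈2.3 M events for the tap campaign, ≈18 M for the river
  campaign), chosen to match the campaigns' published scale while keeping
  a complete two-campaign analysis in the order of a minute.

## Known limitations

- The default gate coordinates are a convention, not the study's gates.
- Ward on 1 − r is a display-ordering heuristic, not a statistically
  grounded clustering of parameters.
- The fixed-band detector has no changepoint model; slow shifts fragment
  near the threshold, and the baseline profile must come from a subset
  that genuinely excludes events.
- p-values assume independent observations; 15-min environmental series
  are autocorrelated, so significance levels are optimistic (the type-I
  calibration test uses independent draws by construction).
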