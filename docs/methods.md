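# Methods

This note documents the models, parameter choices and numerical conventions
behind `iaq`, and what the synthetic test conditions do and do not show.

## Index model

The indoor AQI is a weighted arithmetic mean `Σ W_i P_i / Σ W_i` over the
six lifestyle pollutants (PM2.5, tVOC, CO2, O3, CO, PM10). Two properties
follow directly and are enforced as tests: the value is a convex combination
of the readings (min ≤ AQI ≤ max, equality when all readings agree), and it
is homogeneous of degree one (scaling all readings scales the index).
Pollutants absent from a reading map drop out of numerator and denominator
alike, so partial sensor sets degrade gracefully rather than biasing the
index toward zero.

The readings enter in **raw canonical units without conversion** — µg/m³
for the particulates and O3, ppm for CO and CO2, ppb for tVOC. This is a
deliberate property of the index definition, not an oversight: the weights
are derived on the same raw scales, so each term `W_i·P_i` is a
dimensionless multiple of that pollutant's IAQI ladder. Sulfur dioxide and
nitrogen dioxide, being predominantly outdoor pollutants, are excluded from
the indoor index; the exclusion is a fixed default with the weight map as
the escape hatch (any pollutant→weight mapping can be passed to
`compute_aqi`).

## Reference tables

The reference bundle (JSON package resource) carries three table families:

* **IAQI breakpoints** per pollutant × averaging window (1 h / 8 h / 24 h),
  strictly increasing in both level and concentration, first row (0, 0).
  Two footnote rules are encoded as window fallbacks: the 1-hour SO2 scale
  above level 200 defers to the 24-hour scale, and the 8-hour O3 scale
  above level 300 defers to the 1-hour scale.
* **Representation constants** (concentration threshold means, PCM). For
  breakpoint-scale pollutants these are the breakpoints themselves —
  validated at load time. For tVOC and CO2 they are published mean-column
  values shipped verbatim: they are close to, but not exactly, band
  midpoints (e.g. tVOC 275 vs the arithmetic midpoint 275.5; the CO2 means
  follow no reproducible midpoint rule), so no re-derivation is attempted
  and a clearly-labelled `band_midpoint` helper exists for exploration only.
* **Health bands** with qualitative labels and IAQI ranges. Band bounds are
  inclusive on both printed ends; values in the gap between printed integer
  bands (e.g. 200.5 between an upper edge of 200 and a lower edge of 201)
  map to the lower, healthier band — the gaps are artifacts of integer
  printing. Values above the top band stay in the top band, making the
  classification total on [0, ∞).

Carbon monoxide appears on two band scales in the sources — a 4-band
mass-concentration scale and a 6-band ppm scale. The ppm scale matches CO's
canonical unit and drives `band_for`; the mass scale ships under the
separate id `co_mass` (with the generic particulate column as `pm`) so both
sources are preserved verbatim without a unit conversion that the raw-scale
arithmetic would forbid. Oxygen's band column is a *descending* scale that
overlaps at its printed edges; it cannot satisfy the non-overlap invariant
band classification relies on and is not shipped as a band set.

## Weightage derivation

Per-level weight `w_r = IAQI_r / PCM_r`; final weight = unweighted mean over
the levels the pollutant defines (tVOC 4, CO2 6, others 7). Level 0 would
contribute a zero weight and is not part of the published worksheets, so it
is omitted — including it would shrink every final weight by `n/(n+1)` and
no longer reproduce the published values. All arithmetic is double
precision; assertions against printed 9-digit decimals use absolute
tolerance 1e-6 since the printed values are truncated.

## Dashboard labels and gauge

The US-gauge categories use the standard six cut points with boundaries
belonging to the lower band. The 4-way GOOD/MODERATE/POOR/BAD tile labels
need three edges per pollutant; published sources state safe and extreme
bounds but never a complete 4-way cut, so the defaults encode the stated
bounds where they exist — tVOC 200/660/2200 ppb (safe / moderate top /
extreme), CO2 GOOD ≤ 1000 ppm (safe ventilated range), PM2.5 GOOD ≤ 35
µg/m³ (the EPA 24-hour limit) — and fall back to IAQI breakpoint levels for
the remaining edges (PM2.5 75/150, PM10 50/150/350, CO 2/9/30.4 from its
ppm band scale, O3 160/200/400 µg/m³; CO2 MODERATE ≤ 2000 and POOR ≤ 5000
from its band scale). Every edge is configuration-overridable; ties map to
the healthier label everywhere.

## Exposure analytics

Exposure cards are sample means over trailing windows, half-open
`(as_of − w, as_of]`, default card set {8 h, 24 h, 72 h, 1 week}. The mean
is over samples present, not time-weighted: streams are user-frequency
sampled and may have outage gaps, and the unweighted mean matches a plain
average of stored rows. (A time-weighted mean would differ on irregular
grids; the sample mean is the simpler reading of a cumulative average and
is the documented choice.) Quarterly displays bucket in-quarter samples to
daily means by default. All timestamps are stored UTC.

Alerts fire for registered users at the first sample of each contiguous run
strictly above the pollutant's threshold. A minimum re-alert interval
(default 1 hour) suppresses a new episode starting sooner after the last
alert — a conservative debounce so flapping around a threshold cannot flood
the sinks. The built-in sink is a structured log line / CSV row; real
email/SMS delivery is out of scope, and sinks are injectable.

## Calibration

One independent OLS model per channel, predicting the reference from the
raw reading (`reference ≈ slope·raw + intercept`), fitted closed-form via
`scipy.stats.linregress` and cross-checked in the tests against a direct
normal-equations solve to 1e-9. The direction (reference-from-raw rather
than raw-toward-reference) means applying the model *is* the correction.
Burn-in gates calibration at exactly ≥ 48 h powered; recalibration is due
at exactly ≥ 90 days; both comparisons are inclusive at the boundary.
Negative corrected values are clamped to zero and flagged, never silently
dropped. The outdoor-station calibration variant is the same fit with a
different reference source — a data-loading concern, not a new algorithm.

Accuracy = mean relative agreement, `100·(1 − mean(|c − ref|/ref))`, floored
at 0, with zero-reference samples excluded (undefined relative error) and an
error raised if nothing remains. This is an interpretation: "percent
accuracy against a reference" has no single standard formula, and mean
relative agreement is the natural reading for paired concentration series.

## Synthetic data

The generator emulates the features the pipeline must survive, not any
particular recorded trace:

* **Baselines** are smooth diurnal sinusoids per channel, anchored only to
  qualitative published ranges: `us_home_winter` accumulates CO2 above
  1000 ppm overnight (closed windows) and recovers below it by day, with
  humidity inside the ideal 30–50% band; `airplane_cabin` is persistently
  below 30% humidity with elevated CO2; `india_home` carries a tVOC
  baseline well above the 0–200 ppb safe range with warm, humid conditions.
* **Activity events** (cooking, cleaning, commuting, ventilation changes)
  add a pulse per pollutant: linear rise over the event duration to a peak
  increment, then exponential decay with a configurable half-life (default
  30 min). The shape is a modelling choice matching the qualitative
  sharp-rise/sustained-elevation pattern of activity traces; pulses
  superpose linearly, which the tests exploit as an invariant.
* **Distortion**: observed = `(gain·true + offset) ×` mean-one log-normal
  noise with coefficient of variation `noise_cv`. Multiplicative noise is
  sensor-like and keeps values positive. One seeded NumPy generator per
  scenario makes output byte-identical across runs with the same config.

`calibration_fixture` draws reference concentrations **log-uniformly** over
(20, 2000) by default. The shape matters: with multiplicative noise on the
raw regressor, OLS suffers errors-in-variables attenuation of order
`cv²·E[x²]/Var(x)`. For any uniform draw that moment ratio is ≥ 4, putting
the slope bias at ≥ 1% for 5% noise regardless of range; a heavy-tailed
lognormal fixes the ratio but lets rare large draws dominate the fit at
individual seeds. The log-uniform's right-skewed, bounded two-decade sweep
keeps the ratio near 1.7 (bias ≈ 0.4%) with no leverage outliers — measured
over 100 seeded replicates at 5% noise and n = 360, the median absolute
slope error is ≈ 0.6% and the worst seed ≈ 1.8%.

**What passing tests show, and what they do not.** The synthetic conditions
establish that the pipeline's logic is correct: weights reproduce the
published worksheets, the index obeys its algebraic properties, alerts
match run-length oracles, and the calibration layer recovers a linear
distortion to high accuracy under its own generating model. They do not
show that real MQ sensors are linear (they drift with temperature and
humidity and cross-react between gases), that real indoor dynamics are
sinusoids plus pulses, or that the ≈95% synthetic postcalibration agreement
transfers to any particular hardware. Covariate corrections
(temperature/humidity terms, adaptive thresholds, learned weights) are
explicitly out of scope.

## Problem sizes

The shipped test and acceptance configurations use 360 calibration pairs
over 15 simulated days with 100 held-out samples, 1000-map property sweeps
for the index, and day-scale scenarios at 5–15-minute sampling — sizes at
which every check runs in seconds while the statistical properties (OLS
recovery, oracle equivalences) are already stable.

## Known limitations

* The weighted-mean index has no piecewise-linear IAQI interpolation; it is
  not the US EPA AQI and values are not comparable across the two schemes.
* Mixed-unit readings mean the index is sensitive to each pollutant's unit
  convention; readings must arrive in canonical units.
* The calibration model is strictly linear per channel — no cross-channel
  terms, no environmental covariates.
* Payload schemas define full key sets; deployments with other sensor key
  spellings must extend `SENSOR_KEYS` (unknown keys are preserved as
  extras, not dropped).
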