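# iaq — a personal indoor air-quality engine

`iaq` turns multi-pollutant indoor sensor streams into actionable air-quality
information: a single weighted-mean indoor AQI, per-pollutant health
classifications and dashboard labels, exposure averages over configurable
windows, threshold alerts, and a linear-regression correction layer for
low-cost metal-oxide (MQ-series) gas sensors. It is aimed at researchers and
tinkerers building personal exposure monitors from consumer-grade sensors,
where hardware is cheap but uncalibrated and the interesting signal is how
everyday activities — cooking, cleaning, commuting, closing the windows in
winter — drive indoor pollution.

Because real deployments need hardware, the package ships a seeded synthetic
stream generator (diurnal location baselines, activity spike pulses, linear
gain/offset sensor distortion with multiplicative noise) so every stage of
the pipeline runs end-to-end on a laptop with no device attached.

## The model

**Indoor AQI.** The index over the six lifestyle pollutants — PM2.5, tVOC,
CO2, O3, CO, PM10 — is the weighted mean of the current (1-hour mean)
readings *P_i*:

```
AQI = Σ W_i · P_i / Σ W_i
```

Readings enter in each pollutant's canonical unit (µg/m³, ppm, ppb) without
conversion; missing pollutants drop out of both sums, so the index is always
a convex combination of the supplied readings.

**Weightages.** Each pollutant's weight is derived from its Individual AQI
(IAQI) scale: at index level *r* with concentration threshold mean *PCM_r*,
the per-level weight is the fractional contribution

```
w_r = IAQI_r / PCM_r
```

and the final weight *W_p* is the arithmetic mean of the per-level weights
over the levels the pollutant's scale defines. The shipped reference bundle
reproduces the published worksheets exactly:

| pollutant | levels | final weight W_p |
|-----------|-------:|-----------------:|
| PM10      | 7      | 0.740816327 |
| CO        | 7      | 5.37414966  |
| O3        | 7      | 0.429166667 |
| PM2.5     | 7      | 1.248920438 |
| tVOC      | 4      | 0.522203583 |
| CO2       | 6      | 0.074724826 |

**Calibration.** A low-cost channel reads `raw = gain·true + offset` plus
multiplicative noise. After a 48-hour powered burn-in, raw readings are
paired daily with a co-located reference instrument over a 15-day window and
an ordinary-least-squares line `reference ≈ slope·raw + intercept` is
fitted per channel; models are refreshed every 90 days. Accuracy is scored
as mean relative agreement, `100·(1 − mean(|corrected − ref|/ref))`.

## Worked example

Compute the AQI for a set of current readings (each at its own IAQI-50
breakpoint except CO2 at its level-50 representation):

```
$ iaq aqi --reading pm25=35 --reading pm10=50 --reading co=5 \
          --reading o3=160 --reading tvoc=100 --reading co2=341
{
 "aqi": 30.273,
 "category": "Good",
 "pollutants": {
  "pm25": {"reading": 35.0, "weight": 1.248920438, "unit": "ug/m3", "label": "GOOD"},
  "pm10": {"reading": 50.0, "weight": 0.740816327, "unit": "ug/m3", "label": "GOOD"},
  "co":   {"reading": 5.0,  "weight": 5.37414966,  "unit": "ppm",   "label": "MODERATE"},
  "o3":   {"reading": 160.0,"weight": 0.429166667, "unit": "ug/m3", "label": "GOOD"},
  "tvoc": {"reading": 100.0,"weight": 0.522203583, "unit": "ppb",   "label": "GOOD"},
  "co2":  {"reading": 341.0,"weight": 0.074724826, "unit": "ppm",   "label": "GOOD"}
 }
}
```

The value 30.27 is the weighted mean of the six readings: CO's large weight
(5.37) pulls the index toward its small ppm reading, while CO2's small
weight (0.075) keeps its large ppm reading from dominating — the weighting
is what makes a mixed-unit mean behave sensibly. The gauge category follows
the US AQI convention (0–50 Good, 51–100 Moderate, …, >300 Hazardous), and
each tile also gets a 4-way GOOD/MODERATE/POOR/BAD label from configurable
per-pollutant edges.

The same library surface is available in Python:

```python
from iaq import compute_aqi, default_weights
result = compute_aqi({"pm25": 35, "co2": 341}, default_weights())
print(result.value, result.category)
```

Other subcommands: `iaq simulate` (synthetic scenario → CSV / JSON payload
stream), `iaq calibrate` (pairs CSV → model JSON), `iaq exposure`
(8h/24h/72h/1-week exposure cards), `iaq alerts` (threshold scan →
alert events), `iaq export` (store → normalized CSV).

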