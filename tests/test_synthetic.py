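"""Synthetic scenario generator: determinism, pulses, profiles, distortion."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from iaq.aqi import dashboard_label
from iaq.calibration import accuracy_score, apply_calibration, fit_calibration
from iaq.exposure import detect_alerts, window_average
from iaq.synthetic import (
    ActivityEvent,
    ScenarioConfig,
    SensorDistortion,
    baseline_profile,
    calibration_fixture,
    event_pulse,
    generate_scenario,
)


def values(series):
    return [v for _, v in series.samples]


def test_identical_seeds_identical_output(t0):
    def build():
        return generate_scenario(
            ScenarioConfig(
                seed=123,
                duration=4 * 3600,
                sampling_interval=600,
                events=[
                    ActivityEvent(
                        "cooking", t0 + timedelta(hours=1), 1800, {"pm25": 80.0}
                    )
                ],
                distortions={"pm25": SensorDistortion(1.2, 5, 0.05)},
            )
        )

    a, b = build(), build()
    for channel in a.observed_series:
        assert values(a.observed_series[channel]) == values(b.observed_series[channel])
    c = generate_scenario(ScenarioConfig(seed=124, duration=4 * 3600,
                                         sampling_interval=600,
                                         distortions={"pm25": SensorDistortion(1.2, 5, 0.05)}))
    assert values(a.observed_series["pm25"]) != values(c.observed_series["pm25"])


def test_no_events_no_noise_identity_observed_equals_baseline(t0):
    config = ScenarioConfig(seed=0, duration=2 * 3600, sampling_interval=300)
    result = generate_scenario(config)
    for channel in result.true_series:
        assert values(result.true_series[channel]) == values(
            result.observed_series[channel]
        )


def test_flat_custom_profile_is_constant(t0):
    config = ScenarioConfig(
        seed=0, duration=3600, sampling_interval=60, custom_baselines={"tvoc": 7.0}
    )
    result = generate_scenario(config)
    assert set(result.true_series) == {"tvoc"}
    assert all(v == 7.0 for v in values(result.true_series["tvoc"]))


def test_pulse_shape_linear_rise_then_exponential_decay(t0):
    event = ActivityEvent(
        "cleaning", t0, duration=600, peak_deltas={"tvoc": 100.0}, decay_halflife=300
    )
    assert event_pulse(event, "tvoc", t0 - timedelta(seconds=1)) == 0.0
    assert event_pulse(event, "tvoc", t0 + timedelta(seconds=300)) == pytest.approx(50.0)
    assert event_pulse(event, "tvoc", t0 + timedelta(seconds=600)) == pytest.approx(100.0)
    # one half-life after release ends: half the peak
    assert event_pulse(event, "tvoc", t0 + timedelta(seconds=900)) == pytest.approx(50.0)
    assert event_pulse(event, "tvoc", t0 + timedelta(seconds=1200)) == pytest.approx(25.0)
    assert event_pulse(event, "other", t0 + timedelta(seconds=300)) == 0.0


def test_event_superposition(t0):
    ev1 = ActivityEvent("cooking", t0 + timedelta(hours=1), 1800, {"pm25": 60.0})
    ev2 = ActivityEvent("cleaning", t0 + timedelta(hours=2), 900, {"pm25": 40.0})

    def trues(events):
        cfg = ScenarioConfig(
            seed=0, duration=4 * 3600, sampling_interval=300, events=events
        )
        return np.array(values(generate_scenario(cfg).true_series["pm25"]))

    base = trues([])
    together = trues([ev1, ev2])
    separate = (trues([ev1]) - base) + (trues([ev2]) - base) + base
    np.testing.assert_allclose(together, separate, atol=1e-9)


@pytest.mark.parametrize("name", ["us_home_winter", "india_home", "airplane_cabin"])
def test_known_profiles_load(name):
    profile = baseline_profile(name)
    assert {"co2", "tvoc", "temperature", "humidity"} <= set(profile)


def test_unknown_profile_raises():
    with pytest.raises(LookupError):
        baseline_profile("moon_base")


def test_airplane_cabin_is_dry():
    result = generate_scenario(
        ScenarioConfig(seed=0, duration=24 * 3600, sampling_interval=600,
                       location_profile="airplane_cabin")
    )
    humidity = values(result.true_series["humidity"])
    assert sum(v < 30 for v in humidity) / len(humidity) > 0.9


def test_us_winter_home_co2_exceeds_1000_overnight():
    result = generate_scenario(
        ScenarioConfig(seed=0, duration=24 * 3600, sampling_interval=600)
    )
    co2 = values(result.true_series["co2"])
    humidity = values(result.true_series["humidity"])
    assert max(co2) > 1000  # closed-window accumulation
    assert min(co2) < 1000  # ventilated daytime recovery
    assert all(30 <= v <= 50 for v in humidity)


def test_india_home_has_elevated_tvoc():
    result = generate_scenario(
        ScenarioConfig(seed=0, duration=24 * 3600, sampling_interval=600,
                       location_profile="india_home")
    )
    tvoc = np.mean(values(result.true_series["tvoc"]))
    assert tvoc > 500  # well above the 0-200 ppb safe range


def test_cleaning_spike_reaches_poor_tvoc_hourly_mean(t0):
    """A cleaning event pushing the 1-h tVOC mean to ~1549 ppb labels POOR."""
    event = ActivityEvent(
        "cleaning",
        t0 + timedelta(hours=6),
        duration=1800,
        peak_deltas={"tvoc": 2600.0},
        decay_halflife=2400,
    )
    result = generate_scenario(
        ScenarioConfig(seed=0, duration=8 * 3600, sampling_interval=300,
                       events=[event])
    )
    hourly = window_average(
        result.true_series["tvoc"], 3600, t0 + timedelta(hours=7)
    )
    assert 1000 < hourly.mean < 2200
    assert dashboard_label("tvoc", hourly.mean).label == "POOR"


def test_cooking_event_fires_pm25_alert(t0):
    event = ActivityEvent(
        "cooking",
        t0 + timedelta(hours=2),
        duration=3600,
        peak_deltas={"pm25": 150.0},
        decay_halflife=3600,
    )
    result = generate_scenario(
        ScenarioConfig(seed=0, duration=8 * 3600, sampling_interval=300,
                       events=[event])
    )
    events = detect_alerts(result.true_series["pm25"], {"pm25": 35.0})
    assert len(events) >= 1
    assert events[0].timestamp >= t0 + timedelta(hours=2)


# -- calibration fixture -------------------------------------------------

def test_noiseless_fixture_recovered_exactly():
    pairs, (slope, intercept) = calibration_fixture(1.3, 10, 0.0, 50, seed=1)
    model = fit_calibration(pairs)
    assert model.slope == pytest.approx(slope, abs=1e-9)
    assert model.intercept == pytest.approx(intercept, abs=1e-9)


def test_identity_transform_slope_near_one():
    pairs, _ = calibration_fixture(1.0, 0.0, 0.05, 360, seed=3)
    model = fit_calibration(pairs)
    assert model.slope == pytest.approx(1.0, rel=0.02)
    assert model.intercept == pytest.approx(0.0, abs=10)


def test_accuracy_approaches_100_as_noise_vanishes():
    scores = []
    for cv in (0.10, 0.02, 0.0):
        pairs, _ = calibration_fixture(1.3, 10, cv, 200, seed=5)
        model = fit_calibration(pairs)
        held, _ = calibration_fixture(1.3, 10, cv, 100, seed=6)
        corrected, _ = apply_calibration(model, [p.raw for p in held])
        scores.append(accuracy_score(corrected, [p.reference for p in held]))
    assert scores[0] < scores[1] < scores[2]
    assert scores[2] == pytest.approx(100.0, abs=1e-6)


def test_fixture_spans_accumulation_window():
    pairs, _ = calibration_fixture(1.3, 10, 0.05, 360, seed=42)
    span = (pairs[-1].timestamp - pairs[0].timestamp).total_seconds()
    assert span <= 15 * 86400
    assert span > 14 * 86400
    assert len(pairs) == 360


def test_fixture_validation():
    with pytest.raises(ValueError):
        calibration_fixture(1.0, 0.0, 0.0, 1, seed=0)
    with pytest.raises(ValueError):
        SensorDistortion(gain=0.0)
    with pytest.raises(ValueError):
        SensorDistortion(noise_cv=-0.1)
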