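"""Synthetic multi-pollutant indoor sensor streams.

Physical hardware is replaced by a seeded generator that emulates the
features of real indoor streams the rest of the pipeline must handle:

* **Location baselines** — smooth diurnal profiles per pollutant and
  environmental parameter.  The shipped profiles are anchored only to
  published qualitative ranges: a US home in winter accumulates CO2 above
  1000 ppm overnight with windows closed and sits in the ideal 30–50%
  humidity band; an airplane cabin is persistently dry (below 30% humidity)
  with elevated CO2; an Indian urban home carries elevated tVOC and high
  humidity/temperature.
* **Activity events** — cooking, cleaning, commuting and ventilation changes
  add a pulse per pollutant: a linear rise over the event duration to a peak
  increment, then exponential decay with a configurable half-life.  Pulses
  superpose linearly.  (The shape is a modelling choice matching the
  qualitative "sharp transient rise, sustained elevation" pattern of real
  activity traces; all parameters are configurable.)
* **Sensor distortion** — each observed channel is ``gain·true + offset``
  scaled by mean-one multiplicative log-normal noise (sensor-like, keeps
  values positive).  This is the miscalibration the correction layer of
  :mod:`iaq.calibration` learns to invert.

Identical seeds and configs yield identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Callable, Mapping, Sequence

import numpy as np

from .calibration import ACCUMULATION_DAYS, CalibrationPair
from .exposure import ReadingSeries

__all__ = [
    "SensorDistortion",
    "ActivityEvent",
    "ScenarioConfig",
    "ScenarioResult",
    "baseline_profile",
    "generate_scenario",
    "event_pulse",
    "calibration_fixture",
    "PROFILE_NAMES",
]

#: Activity kinds with packaged default pulse shapes.
EVENT_KINDS = ("cooking", "cleaning", "commuting", "ventilation_change", "custom")


@dataclass(frozen=True)
class SensorDistortion:
    """Linear miscalibration plus multiplicative noise for one channel."""

    gain: float = 1.0
    offset: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def inverse(self) -> tuple[float, float]:
        """(slope, intercept) of the exact corrective line for this channel."""
        return 1.0 / self.gain, -self.offset / self.gain


@dataclass(frozen=True)
class ActivityEvent:
    """A pollutant-releasing activity: linear rise then exponential decay."""

    kind: str
    start: datetime
    duration: int  # seconds of active release
    peak_deltas: Mapping[str, float]  # pollutant -> peak increment
    decay_halflife: int = 1800  # seconds

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0 or self.decay_halflife <= 0:
            raise ValueError("duration and decay_halflife must be > 0")
        if any(v < 0 for v in self.peak_deltas.values()):
            raise ValueError("peak_deltas must be >= 0")


def event_pulse(event: ActivityEvent, pollutant: str, at: datetime) -> float:
    """The event's additive contribution to one pollutant at one instant."""
    delta = event.peak_deltas.get(pollutant, 0.0)
    if delta == 0.0:
        return 0.0
    dt = (at - event.start).total_seconds()
    if dt < 0:
        return 0.0
    if dt <= event.duration:
        return delta * dt / event.duration
    return delta * math.exp(-math.log(2) * (dt - event.duration) / event.decay_halflife)


@dataclass
class ScenarioConfig:
    """Everything that determines a generated scenario (seed included)."""

    seed: int
    duration: int = 24 * 3600  # seconds
    sampling_interval: int = 300  # seconds
    location_profile: str = "us_home_winter"
    start: datetime = field(
        default_factory=lambda: datetime(2021, 1, 4, 0, 0, tzinfo=timezone.utc)
    )
    events: list[ActivityEvent] = field(default_factory=list)
    distortions: dict[str, SensorDistortion] = field(default_factory=dict)
    custom_baselines: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    true_series: dict[str, ReadingSeries]
    observed_series: dict[str, ReadingSeries]
    events: list[ActivityEvent]


# -- location baselines --------------------------------------------------

def _diurnal(mean: float, amplitude: float, peak_hour: float) -> Callable[[float], float]:
    def f(hour: float) -> float:
        return mean + amplitude * math.cos(2 * math.pi * (hour - peak_hour) / 24.0)

    return f


_PROFILES: dict[str, dict[str, Callable[[float], float]]] = {
    # Closed windows overnight: CO2 peaks above 1000 ppm in the small hours,
    # humidity in the ideal 30-50% band, low pollutant background.
    "us_home_winter": {
        "co2": _diurnal(800.0, 350.0, peak_hour=4.0),
        "tvoc": _diurnal(90.0, 30.0, peak_hour=19.0),
        "pm25": _diurnal(8.0, 3.0, peak_hour=19.0),
        "pm10": _diurnal(18.0, 5.0, peak_hour=19.0),
        "o3": _diurnal(30.0, 10.0, peak_hour=14.0),
        "co": _diurnal(0.5, 0.2, peak_hour=19.0),
        "temperature": _diurnal(21.0, 1.5, peak_hour=16.0),
        "humidity": _diurnal(40.0, 6.0, peak_hour=6.0),
    },
    # Elevated tVOC background, warm and humid.
    "india_home": {
        "co2": _diurnal(620.0, 120.0, peak_hour=5.0),
        "tvoc": _diurnal(700.0, 180.0, peak_hour=18.0),
        "pm25": _diurnal(45.0, 12.0, peak_hour=19.0),
        "pm10": _diurnal(90.0, 20.0, peak_hour=19.0),
        "o3": _diurnal(45.0, 15.0, peak_hour=14.0),
        "co": _diurnal(0.9, 0.3, peak_hour=19.0),
        "temperature": _diurnal(30.0, 3.0, peak_hour=15.0),
        "humidity": _diurnal(55.0, 9.0, peak_hour=6.0),
    },
    # Persistently dry recirculated cabin air with elevated CO2.
    "airplane_cabin": {
        "co2": _diurnal(1050.0, 120.0, peak_hour=12.0),
        "tvoc": _diurnal(100.0, 20.0, peak_hour=12.0),
        "pm25": _diurnal(5.0, 1.5, peak_hour=12.0),
        "pm10": _diurnal(10.0, 2.0, peak_hour=12.0),
        "o3": _diurnal(25.0, 5.0, peak_hour=12.0),
        "co": _diurnal(0.4, 0.1, peak_hour=12.0),
        "temperature": _diurnal(23.0, 0.8, peak_hour=14.0),
        "humidity": _diurnal(18.0, 4.0, peak_hour=3.0),
    },
}

PROFILE_NAMES = tuple(_PROFILES)


def baseline_profile(name: str) -> dict[str, Callable[[float], float]]:
    """Per-channel baseline functions of hour-of-day for a named location."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise LookupError(
            f"unknown profile {name!r}; known: {', '.join(PROFILE_NAMES)}"
        ) from None


# -- scenario generation -------------------------------------------------

def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def generate_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Generate true and distorted (observed) series for every channel.

    The true value of channel c at time t is ``baseline_c(hour of day) +
    sum of event pulses``; the observed value passes through the channel's
    :class:`SensorDistortion`.  Identical configs (seed included) produce
    identical output.
    """
    if config.custom_baselines is not None:
        baselines: dict[str, Callable[[float], float]] = {
            ch: (lambda h, v=v: v) for ch, v in config.custom_baselines.items()
        }
    else:
        baselines = baseline_profile(config.location_profile)

    n = config.duration // config.sampling_interval
    times = [
        config.start + timedelta(seconds=i * config.sampling_interval)
        for i in range(n)
    ]
    rng = np.random.default_rng(config.seed)

    true_series: dict[str, ReadingSeries] = {}
    observed_series: dict[str, ReadingSeries] = {}
    for channel in baselines:  # dict order is deterministic
        base = baselines[channel]
        true_vals = np.array(
            [
                max(
                    0.0,
                    base(t.hour + t.minute / 60.0 + t.second / 3600.0)
                    + sum(event_pulse(ev, channel, t) for ev in config.events),
                )
                for t in times
            ]
        )
        distortion = config.distortions.get(channel, SensorDistortion())
        observed_vals = (
            distortion.gain * true_vals + distortion.offset
        ) * _noise_factors(rng, distortion.noise_cv, n)
        observed_vals = np.maximum(observed_vals, 0.0)
        true_series[channel] = ReadingSeries(
            channel, list(zip(times, true_vals)), config.sampling_interval
        )
        observed_series[channel] = ReadingSeries(
            channel, list(zip(times, observed_vals)), config.sampling_interval
        )
    return ScenarioResult(config, true_series, observed_series, list(config.events))


# -- calibration fixtures ------------------------------------------------

def calibration_fixture(
    gain: float,
    offset: float,
    noise_cv: float,
    n: int,
    seed: int,
    reference_range: tuple[float, float] = (20.0, 2000.0),
    accumulation_days: int = ACCUMULATION_DAYS,
    start: datetime | None = None,
) -> tuple[list[CalibrationPair], tuple[float, float]]:
    """Paired raw/reference calibration data with known ground truth.

    Reference concentrations are drawn log-uniformly over
    ``reference_range`` — a right-skewed sweep across two decades, as a
    calibration run moving between clean-air background and activity
    episodes sees — and the raw channel observes ``(gain·reference +
    offset)`` under the same mean-one multiplicative noise model as
    :func:`generate_scenario`.  Pairs are spread evenly over
    ``accumulation_days`` days of daily accumulation.

    Returns ``(pairs, (slope, intercept))`` where the slope/intercept are the
    exact corrective line ``reference = (raw - offset) / gain`` an ideal fit
    should recover.  (Noise on the raw regressor attenuates the fitted slope
    by roughly ``noise_cv²·E[raw²]/Var(raw)``; the log-uniform's spread and
    bounded support keep that bias and the leverage of large draws well
    under the noise level itself.)
    """
    if n < 2:
        raise ValueError("need n >= 2 calibration pairs")
    if not (0 < reference_range[0] < reference_range[1]):
        raise ValueError("reference_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    start = start or datetime(2021, 1, 4, 8, 0, tzinfo=timezone.utc)
    reference = np.exp(
        rng.uniform(math.log(reference_range[0]), math.log(reference_range[1]), size=n)
    )
    raw = (gain * reference + offset) * _noise_factors(rng, noise_cv, n)
    step = accumulation_days * 86400 / n
    pairs = [
        CalibrationPair(start + timedelta(seconds=i * step), float(r), float(ref))
        for i, (r, ref) in enumerate(zip(raw, reference))
    ]
    return pairs, SensorDistortion(gain, offset, noise_cv).inverse()
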