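"""Exposure analytics: windowed averages, quarterly series, threshold alerts.

Average exposure is the sample mean of the readings falling in a trailing
window — half-open ``(as_of - window, as_of]`` — over the default card set of
8 hours, 24 hours, 72 hours and 1 week (configurable).  Sampling may be
irregular (outages, user-chosen frequency); means are unweighted over the
samples present, matching a plain mean of stored rows.  All timestamps are
UTC.

Alerting follows the validate-then-notify flow: readings are compared with
predetermined safety thresholds and, for a registered user, one alert event
is raised at the first sample of each contiguous exceedance episode, with a
minimum re-alert interval (default 1 hour) so flapping streams do not flood
the sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReadingSeries",
    "ExposureSummary",
    "AlertEvent",
    "DEFAULT_WINDOWS",
    "window_average",
    "exposure_summaries",
    "quarterly_series",
    "detect_alerts",
]

#: Default exposure-card windows, label -> seconds.
DEFAULT_WINDOWS: dict[str, int] = {
    "8h": 8 * 3600,
    "24h": 24 * 3600,
    "72h": 72 * 3600,
    "1week": 7 * 24 * 3600,
}


def _as_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass
class ReadingSeries:
    """A time-ordered single-pollutant stream of validated readings."""

    pollutant: str
    samples: list[tuple[datetime, float]]
    sampling_interval: int | None = None  # seconds, informational

    def __post_init__(self) -> None:
        self.samples = [(_as_utc(t), float(v)) for t, v in self.samples]
        for i, (t, v) in enumerate(self.samples):
            if v < 0:
                raise ValueError(f"sample {i}: negative value {v}")
            if i and t <= self.samples[i - 1][0]:
                raise ValueError(f"sample {i}: timestamps must be strictly increasing")

    def extend(self, samples: Iterable[tuple[datetime, float]]) -> None:
        for t, v in samples:
            t = _as_utc(t)
            if v < 0:
                raise ValueError(f"negative value {v}")
            if self.samples and t <= self.samples[-1][0]:
                raise ValueError("timestamps must be strictly increasing")
            self.samples.append((t, float(v)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.samples, columns=["timestamp", "value"]
        ).set_index("timestamp")


@dataclass(frozen=True)
class ExposureSummary:
    pollutant: str
    window: str
    mean: float
    n_samples: int


@dataclass(frozen=True)
class AlertEvent:
    pollutant: str
    timestamp: datetime
    value: float
    threshold_exceeded: float
    severity: str
    channel: str = "log"


def window_average(
    series: ReadingSeries,
    window: str | int,
    as_of: datetime,
    windows: Mapping[str, int] = DEFAULT_WINDOWS,
) -> ExposureSummary:
    """Sample mean over the trailing window ``(as_of - window, as_of]``.

    ``window`` is a card label from ``windows`` or a duration in seconds.
    Raises ``LookupError`` when no sample falls inside the window.
    """
    seconds = windows[window] if isinstance(window, str) else int(window)
    label = window if isinstance(window, str) else f"{seconds}s"
    as_of = _as_utc(as_of)
    start = as_of - timedelta(seconds=seconds)
    in_window = [v for t, v in series.samples if start < t <= as_of]
    if not in_window:
        raise LookupError(
            f"no {series.pollutant} samples in the {label} window ending {as_of}"
        )
    return ExposureSummary(
        pollutant=series.pollutant,
        window=label,
        mean=sum(in_window) / len(in_window),
        n_samples=len(in_window),
    )


def exposure_summaries(
    series: ReadingSeries,
    as_of: datetime,
    windows: Mapping[str, int] = DEFAULT_WINDOWS,
) -> list[ExposureSummary]:
    """One summary per card window that contains at least one sample."""
    out = []
    for label in windows:
        try:
            out.append(window_average(series, label, as_of, windows))
        except LookupError:
            continue
    return out


def quarterly_series(
    series: ReadingSeries, quarter: str, resolution: str = "1D"
) -> pd.Series:
    """In-quarter samples bucketed to a display resolution (default daily means).

    ``quarter`` is a calendar-quarter label like ``"2021Q1"``.  Returns an
    empty series when the quarter holds no samples.
    """
    period = pd.Period(quarter, freq="Q")
    frame = series.to_frame()
    if frame.empty:
        return pd.Series(dtype=float, name=series.pollutant)
    start = period.start_time.tz_localize("UTC")
    end = period.end_time.tz_localize("UTC")
    in_q = frame[(frame.index >= start) & (frame.index <= end)]
    if in_q.empty:
        return pd.Series(dtype=float, name=series.pollutant)
    out = in_q["value"].resample(resolution).mean().dropna()
    out.name = series.pollutant
    return out


def detect_alerts(
    series: ReadingSeries,
    thresholds: Mapping[str, float],
    registered: bool = True,
    severity: str | None = None,
    realert_interval: int = 3600,
    channel: str = "log",
) -> list[AlertEvent]:
    """Threshold-exceedance alerts for a registered user.

    One event fires at the first sample of each contiguous run of samples
    strictly above the pollutant's threshold; a new episode starting within
    ``realert_interval`` seconds of the previous alert is suppressed.
    An unconfigured pollutant yields no events.
    """
    if not registered:
        return []
    threshold = thresholds.get(series.pollutant)
    if threshold is None:
        return []
    events: list[AlertEvent] = []
    in_episode = False
    last_alert: datetime | None = None
    for t, v in series.samples:
        if v > threshold:
            if not in_episode:
                in_episode = True
                if (
                    last_alert is None
                    or (t - last_alert).total_seconds() >= realert_interval
                ):
                    events.append(
                        AlertEvent(
                            pollutant=series.pollutant,
                            timestamp=t,
                            value=v,
                            threshold_exceeded=threshold,
                            severity=severity or "threshold exceeded",
                            channel=channel,
                        )
                    )
                    last_alert = t
        else:
            in_episode = False
    return events
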