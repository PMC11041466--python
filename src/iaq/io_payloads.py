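"""Telemetry dialects: sensor JSON payloads, dashboard JSON, CSV, buffering.

Three wire formats move data through the system:

* **Sensor payload** — the JSON a collection device posts upstream: a device
  id, optional user/location context tags (zip code, city, state, country,
  space, room, activity), a timestamp, and flat key→value sensor readings.
  Sensor keys use the device dialect ("PM2.5", "tVOC", "CO2", …); unknown
  keys are preserved as opaque extras and logged, never dropped.
* **Dashboard payload** — the JSON the UI consumes: per-pollutant value,
  unit, label and thresholds, an environmental block (temperature, humidity,
  pressure, altitude) and an AQI block (value, gauge category).
* **CSV export** — long-format rows (timestamp, channel, value, unit, plus
  context tags), RFC 4180 quoting, ISO-8601 UTC timestamps, UTF-8.

A :class:`LocalBuffer` models store-and-forward transmission: payloads
accumulate while offline and drain upstream in timestamp order exactly once;
a transport failure retains the failed payload and everything after it.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .exposure import ReadingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SensorPayload",
    "DashboardPayload",
    "LocalBuffer",
    "SENSOR_KEYS",
    "parse_sensor_payload",
    "serialize_sensor_payload",
    "scenario_payloads",
    "payloads_to_series",
    "export_csv",
    "import_csv",
    "build_dashboard_payload",
    "parse_dashboard_payload",
    "buffer_and_drain",
]

#: Device-dialect sensor keys <-> internal channel ids.
SENSOR_KEYS: dict[str, str] = {
    "PM2.5": "pm25",
    "PM10": "pm10",
    "CO": "co",
    "CO2": "co2",
    "eCO2": "eco2",
    "O3": "o3",
    "tVOC": "tvoc",
    "SO2": "so2",
    "NO2": "no2",
    "NH3": "nh3",
    "H2S": "h2s",
    "Ethanol": "ethanol",
    "Toluene": "toluene",
    "Hydrogen": "hydrogen",
    "Oxygen": "oxygen",
    "HCHO": "hcho",
    "LPG": "lpg",
    "NG": "ng",
    "Methane": "methane",
    "Smoke": "smoke",
    "Flammable": "flammable",
    "Aromatic": "aromatic",
    "Temperature": "temperature",
    "Humidity": "humidity",
    "Pressure": "pressure",
    "Altitude": "altitude",
}
_CHANNEL_TO_KEY = {v: k for k, v in SENSOR_KEYS.items()}

#: Units for environmental (non-pollutant) channels.
ENV_UNITS = {
    "temperature": "degC",
    "humidity": "%",
    "pressure": "hPa",
    "altitude": "m",
}

_CONTEXT_FIELDS = ("zipcode", "city", "state", "country", "space", "room", "activity")


@dataclass
class SensorPayload:
    device_id: str
    timestamp: datetime
    readings: dict[str, float]  # channel id -> value
    context: dict[str, str] = field(default_factory=dict)
    extras: dict[str, object] = field(default_factory=dict)


@dataclass
class DashboardPayload:
    pollutants: dict[str, dict]  # id -> {value, unit, label, thresholds, tips}
    environment: dict[str, dict]  # id -> {value, unit}
    aqi: dict  # {value, category}


def parse_sensor_payload(document: str | Mapping) -> SensorPayload:
    """Parse one device JSON payload into a validated :class:`SensorPayload`.

    Unknown sensor keys are kept under ``extras`` with a log warning; a
    missing timestamp or a non-numeric reading is a ``ValueError`` naming the
    key; malformed JSON raises ``json.JSONDecodeError``.
    """
    doc = json.loads(document) if isinstance(document, str) else dict(document)
    if "timestamp" not in doc:
        raise ValueError("payload missing required field 'timestamp'")
    ts = doc.pop("timestamp")
    timestamp = (
        datetime.fromisoformat(ts) if isinstance(ts, str) else
        datetime.fromtimestamp(ts, tz=timezone.utc)
    )
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    device_id = str(doc.pop("device_id", "unknown"))
    context = {k: str(doc.pop(k)) for k in _CONTEXT_FIELDS if k in doc}
    readings: dict[str, float] = {}
    extras: dict[str, object] = {}
    for key, value in doc.items():
        channel = SENSOR_KEYS.get(key)
        if channel is None:
            logger.warning("unknown sensor key %r preserved as extra", key)
            extras[key] = value
            continue
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ValueError(f"non-numeric reading for key {key!r}: {value!r}")
        readings[channel] = float(value)
    return SensorPayload(device_id, timestamp, readings, context, extras)


def serialize_sensor_payload(payload: SensorPayload) -> str:
    """The device-dialect JSON for a payload (inverse of parsing)."""
    doc: dict[str, object] = {
        "device_id": payload.device_id,
        "timestamp": payload.timestamp.astimezone(timezone.utc).isoformat(),
    }
    for field_name in _CONTEXT_FIELDS:  # canonical tag order
        if field_name in payload.context:
            doc[field_name] = payload.context[field_name]
    for channel, value in payload.readings.items():
        doc[_CHANNEL_TO_KEY.get(channel, channel)] = value
    doc.update(payload.extras)
    return json.dumps(doc)


def scenario_payloads(
    series_map: Mapping[str, ReadingSeries],
    device_id: str = "synthetic-0",
    context: Mapping[str, str] | None = None,
) -> list[SensorPayload]:
    """Fold per-channel series into one payload per timestamp, time-ordered."""
    by_time: dict[datetime, dict[str, float]] = {}
    for channel, series in series_map.items():
        for t, v in series.samples:
            by_time.setdefault(t, {})[channel] = v
    return [
        SensorPayload(device_id, t, readings, dict(context or {}))
        for t, readings in sorted(by_time.items())
    ]


def payloads_to_series(
    payloads: Sequence[SensorPayload],
) -> dict[str, ReadingSeries]:
    """Regroup payloads into one :class:`ReadingSeries` per channel."""
    by_channel: dict[str, list[tuple[datetime, float]]] = {}
    for p in sorted(payloads, key=lambda p: p.timestamp):
        for channel, value in p.readings.items():
            by_channel.setdefault(channel, []).append((p.timestamp, value))
    return {ch: ReadingSeries(ch, samples) for ch, samples in by_channel.items()}


# -- CSV export ----------------------------------------------------------

CSV_COLUMNS = ("timestamp", "channel", "value", "unit") + _CONTEXT_FIELDS


def export_csv(
    series_map: Mapping[str, ReadingSeries],
    path: str | Path,
    units: Mapping[str, str] | None = None,
    context: Mapping[str, str] | None = None,
) -> int:
    """Write the series set as long-format CSV; returns the row count.

    One row per (timestamp, channel, value); fixed column order with header;
    RFC 4180 quoting; ISO-8601 UTC timestamps; full float precision.
    """
    if not series_map:
        raise ValueError("series set must be nonempty")
    units = dict(units or {})
    context = dict(context or {})
    rows = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for channel in sorted(series_map):
            unit = units.get(channel, ENV_UNITS.get(channel, ""))
            for t, v in series_map[channel].samples:
                writer.writerow(
                    [
                        t.astimezone(timezone.utc).isoformat(),
                        channel,
                        repr(v),
                        unit,
                    ]
                    + [context.get(f, "") for f in _CONTEXT_FIELDS]
                )
                rows += 1
    return rows


def import_csv(path: str | Path) -> dict[str, ReadingSeries]:
    """Read an exported CSV back into per-channel series (lossless)."""
    by_channel: dict[str, list[tuple[datetime, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            by_channel.setdefault(row["channel"], []).append(
                (datetime.fromisoformat(row["timestamp"]), float(row["value"]))
            )
    return {ch: ReadingSeries(ch, samples) for ch, samples in by_channel.items()}


# -- dashboard payload ---------------------------------------------------

def build_dashboard_payload(
    pollutants: Mapping[str, Mapping],
    environment: Mapping[str, Mapping],
    aqi: Mapping,
) -> str:
    return json.dumps(
        {
            "pollutants": {k: dict(v) for k, v in pollutants.items()},
            "environment": {k: dict(v) for k, v in environment.items()},
            "aqi": dict(aqi),
        }
    )


def parse_dashboard_payload(document: str) -> DashboardPayload:
    doc = json.loads(document)
    return DashboardPayload(doc["pollutants"], doc["environment"], doc["aqi"])


# -- local buffering and transport ---------------------------------------

class TransportError(RuntimeError):
    """The simulated upstream transport rejected a payload."""


class LocalBuffer:
    """Append-only store-and-forward buffer with exactly-once drain."""

    def __init__(self) -> None:
        self._pending: list[SensorPayload] = []

    def append(self, payload: SensorPayload) -> None:
        self._pending.append(payload)

    def __len__(self) -> int:
        return len(self._pending)

    @property
    def pending(self) -> tuple[SensorPayload, ...]:
        return tuple(self._pending)

    def drain(self, transport: Callable[[SensorPayload], None]) -> list[SensorPayload]:
        """Upload pending payloads in timestamp order, removing each on success.

        On a transport failure the failed payload and everything after it are
        retained for the next drain.
        """
        self._pending.sort(key=lambda p: p.timestamp)
        uploaded: list[SensorPayload] = []
        while self._pending:
            payload = self._pending[0]
            try:
                transport(payload)
            except TransportError:
                logger.warning(
                    "transport failed at %s; %d payloads retained",
                    payload.timestamp,
                    len(self._pending),
                )
                break
            uploaded.append(self._pending.pop(0))
        return uploaded


def buffer_and_drain(
    buffer: LocalBuffer,
    connectivity: bool,
    transport: Callable[[SensorPayload], None],
) -> list[SensorPayload]:
    """Drain the buffer when connectivity is available; otherwise hold."""
    if not connectivity:
        return []
    return buffer.drain(transport)
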