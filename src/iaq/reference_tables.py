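"""Reference tables for the indoor air-quality engine.

The engine is driven by three families of reference data, shipped as a JSON
resource and loaded into validated dataclasses:

* **Breakpoint tables** — for each pollutant and averaging window, the ordered
  (IAQI level, concentration) pairs that anchor the Individual Air Quality
  Index scale.  Sulfur dioxide and ozone carry window-fallback rules: above a
  stated level the short-window scale defers to the companion window.
* **Representation constants** — the single "concentration threshold mean"
  standing for a pollutant at each IAQI level.  For the breakpoint-table
  pollutants this is the breakpoint concentration itself; for tVOC and CO2 it
  is a published mean column that is *not* re-derived (the printed values are
  authoritative and do not follow any exact midpoint rule).
* **Health bands** — per-pollutant concentration ranges with qualitative
  labels (Good … Hazardous) and the IAQI range each band spans.

Concentrations are stored in each pollutant's canonical unit (µg/m³, ppm,
ppb or %) and are never converted between tables: downstream arithmetic uses
the raw table values, as the index definition does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Pollutant",
    "AveragingWindow",
    "BreakpointRow",
    "BreakpointTable",
    "RepresentationTable",
    "HealthBand",
    "ReferenceBundle",
    "load_reference_bundle",
    "default_bundle",
    "AQI_POLLUTANTS",
    "BundleValidationError",
]

#: The six lifestyle pollutants entering the weighted-mean indoor AQI.
#: Sulfur dioxide and nitrogen dioxide are primarily outdoor pollutants and
#: are excluded from the indoor index.
AQI_POLLUTANTS: tuple[str, ...] = ("pm25", "pm10", "co", "o3", "tvoc", "co2")

#: Averaging-window labels mapped to their duration in seconds.
WINDOW_SECONDS: dict[str, int] = {"1h": 3600, "8h": 8 * 3600, "24h": 24 * 3600}


class BundleValidationError(ValueError):
    """A reference table violated an invariant; message names table and row."""


@dataclass(frozen=True)
class Pollutant:
    """A measurable analyte with a fixed canonical unit."""

    id: str
    canonical_unit: str
    display_name: str


@dataclass(frozen=True)
class AveragingWindow:
    label: str
    duration: int  # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise BundleValidationError(f"window {self.label}: duration must be > 0")


@dataclass(frozen=True)
class BreakpointRow:
    iaqi_level: float
    concentration: float


@dataclass(frozen=True)
class BreakpointTable:
    """Ordered (IAQI, concentration) anchors for one pollutant and window."""

    pollutant: str
    window: str
    rows: tuple[BreakpointRow, ...]

    def __post_init__(self) -> None:
        name = f"breakpoints[{self.pollutant}][{self.window}]"
        prev = None
        for i, row in enumerate(self.rows):
            if row.iaqi_level < 0 or row.concentration < 0:
                raise BundleValidationError(f"{name} row {i}: negative value")
            if prev is not None and (
                row.iaqi_level <= prev.iaqi_level
                or row.concentration <= prev.concentration
            ):
                raise BundleValidationError(
                    f"{name} row {i}: rows must be strictly increasing in both "
                    f"IAQI level and concentration"
                )
            prev = row

    def concentration_at(self, iaqi_level: float) -> float:
        for row in self.rows:
            if row.iaqi_level == iaqi_level:
                return row.concentration
        raise LookupError(
            f"no breakpoint at IAQI {iaqi_level} for {self.pollutant}/{self.window}"
        )

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(r.iaqi_level for r in self.rows)


@dataclass(frozen=True)
class RepresentationTable:
    """Per-level concentration threshold means (PCM) for one pollutant.

    ``source_window`` names the breakpoint window the constants coincide with,
    or ``None`` for tVOC/CO2 whose printed means stand on their own.
    """

    pollutant: str
    source_window: str | None
    levels: tuple[tuple[float, float], ...]  # (iaqi_level, representation)

    def __post_init__(self) -> None:
        seen: set[float] = set()
        for lvl, rep in self.levels:
            if lvl in seen:
                raise BundleValidationError(
                    f"representations[{self.pollutant}]: duplicate level {lvl}"
                )
            seen.add(lvl)
            if lvl > 0 and rep <= 0:
                raise BundleValidationError(
                    f"representations[{self.pollutant}] level {lvl}: "
                    f"representation must be > 0"
                )

    def representation_at(self, iaqi_level: float) -> float:
        for lvl, rep in self.levels:
            if lvl == iaqi_level:
                return rep
        raise LookupError(
            f"no representation at IAQI {iaqi_level} for {self.pollutant}"
        )


@dataclass(frozen=True)
class HealthBand:
    """One qualitative concentration band for a pollutant."""

    pollutant: str
    low: float
    high: float
    iaqi_range: tuple[float, float]
    label: str

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise BundleValidationError(
                f"health_bands[{self.pollutant}] '{self.label}': low > high"
            )

    def contains(self, concentration: float) -> bool:
        return self.low <= concentration <= self.high


@dataclass
class ReferenceBundle:
    """The validated reference-table set the rest of the engine consumes."""

    pollutants: dict[str, Pollutant]
    breakpoints: dict[str, dict[str, BreakpointTable]]
    window_fallbacks: list[dict]
    representations: dict[str, RepresentationTable]
    health_bands: dict[str, tuple[HealthBand, ...]] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def pollutant(self, pollutant_id: str) -> Pollutant:
        try:
            return self.pollutants[pollutant_id]
        except KeyError:
            raise LookupError(f"unknown pollutant id {pollutant_id!r}") from None

    def breakpoint_concentration(
        self, pollutant: str, window: str, iaqi_level: float
    ) -> float:
        """Breakpoint concentration, honouring window-fallback footnotes.

        Where a short-window scale is undefined above a level (SO2 1 h above
        200, O3 8 h above 300), the lookup defers to the companion window.
        """
        tables = self.breakpoints.get(pollutant)
        if not tables or window not in tables:
            raise LookupError(f"no breakpoint table for {pollutant}/{window}")
        for rule in self.window_fallbacks:
            if (
                rule["pollutant"] == pollutant
                and rule["window"] == window
                and iaqi_level > rule["above_level"]
            ):
                return self.breakpoint_concentration(pollutant, rule["use"], iaqi_level)
        return tables[window].concentration_at(iaqi_level)

    def representation_for(self, pollutant: str, iaqi_level: float) -> float:
        """The concentration threshold mean PCM for (pollutant, IAQI level)."""
        table = self.representations.get(pollutant)
        if table is None:
            raise LookupError(f"no representation constants for {pollutant!r}")
        return table.representation_at(iaqi_level)

    def band_for(self, pollutant: str, concentration: float) -> HealthBand:
        """The health band containing ``concentration``.

        Bands are inclusive on both printed ends; a value in the gap between
        two printed integer bands (for example 200.5 between an upper edge of
        200 and a lower edge of 201) maps to the lower, healthier band, and a
        value above the top band's upper edge maps to the top band.
        """
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        bands = self.health_bands.get(pollutant)
        if not bands:
            raise LookupError(f"no health bands for {pollutant!r}")
        for band, nxt in zip(bands, bands[1:] + (None,)):
            if band.contains(concentration):
                return band
            # printed-integer gap: below the next band's low -> lower band
            if nxt is not None and band.high < concentration < nxt.low:
                return band
        return bands[-1]

    def band_midpoint(self, pollutant: str, iaqi_level: float) -> float:
        """Arithmetic midpoint of the band whose IAQI range tops at ``iaqi_level``.

        Exploration helper only: the shipped representation constants are the
        published values and are close to, but not exactly, these midpoints.
        """
        for band in self.health_bands.get(pollutant, ()):
            if band.iaqi_range[1] == iaqi_level:
                return (band.low + band.high) / 2.0
        raise LookupError(f"no band topping at IAQI {iaqi_level} for {pollutant}")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pollutants": {
                p.id: {"unit": p.canonical_unit, "display_name": p.display_name}
                for p in self.pollutants.values()
            },
            "breakpoints": {
                pid: {
                    w: [[r.iaqi_level, r.concentration] for r in t.rows]
                    for w, t in tables.items()
                }
                for pid, tables in self.breakpoints.items()
            },
            "window_fallbacks": list(self.window_fallbacks),
            "representations": {
                pid: {"window": t.source_window, "levels": [list(lv) for lv in t.levels]}
                for pid, t in self.representations.items()
            },
            "health_bands": {
                pid: [
                    {
                        "low": b.low,
                        "high": b.high,
                        "iaqi_low": b.iaqi_range[0],
                        "iaqi_high": b.iaqi_range[1],
                        "label": b.label,
                    }
                    for b in bands
                ]
                for pid, bands in self.health_bands.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _build_bundle(doc: Mapping) -> ReferenceBundle:
    pollutants = {
        pid: Pollutant(pid, entry["unit"], entry["display_name"])
        for pid, entry in doc["pollutants"].items()
    }

    def check_pollutant(pid: str, where: str) -> None:
        if pid not in pollutants:
            raise BundleValidationError(f"{where}: unknown pollutant {pid!r}")

    breakpoints: dict[str, dict[str, BreakpointTable]] = {}
    for pid, tables in doc.get("breakpoints", {}).items():
        check_pollutant(pid, "breakpoints")
        breakpoints[pid] = {}
        for window, rows in tables.items():
            if window not in WINDOW_SECONDS:
                raise BundleValidationError(
                    f"breakpoints[{pid}]: unknown window {window!r}"
                )
            breakpoints[pid][window] = BreakpointTable(
                pid, window, tuple(BreakpointRow(lvl, c) for lvl, c in rows)
            )

    representations: dict[str, RepresentationTable] = {}
    for pid, entry in doc.get("representations", {}).items():
        check_pollutant(pid, "representations")
        table = RepresentationTable(
            pid, entry.get("window"), tuple((lvl, rep) for lvl, rep in entry["levels"])
        )
        representations[pid] = table
        if table.source_window is not None:
            # invariant: breakpoint-table pollutants' constants ARE breakpoints
            bp = breakpoints[pid][table.source_window]
            for lvl, rep in table.levels:
                if bp.concentration_at(lvl) != rep:
                    raise BundleValidationError(
                        f"representations[{pid}] level {lvl}: {rep} does not "
                        f"match the {table.source_window} breakpoint"
                    )

    health_bands: dict[str, tuple[HealthBand, ...]] = {}
    for pid, bands in doc.get("health_bands", {}).items():
        check_pollutant(pid, "health_bands")
        built = tuple(
            HealthBand(
                pid,
                b["low"],
                b["high"],
                (b["iaqi_low"], b["iaqi_high"]),
                b["label"],
            )
            for b in bands
        )
        for i in range(1, len(built)):
            if built[i].low <= built[i - 1].high:
                raise BundleValidationError(
                    f"health_bands[{pid}] row {i}: bands overlap or out of order"
                )
        health_bands[pid] = built

    return ReferenceBundle(
        pollutants=pollutants,
        breakpoints=breakpoints,
        window_fallbacks=list(doc.get("window_fallbacks", [])),
        representations=representations,
        health_bands=health_bands,
    )


def load_reference_bundle(source: str | Path | Mapping | None = None) -> ReferenceBundle:
    """Load and validate a reference bundle.

    ``source`` may be a path to a JSON document, an already-parsed mapping, or
    ``None`` for the bundle shipped with the package.  Raises
    :class:`BundleValidationError` naming the offending table and row when an
    invariant fails, and ``json.JSONDecodeError`` on malformed input.
    """
    if source is None:
        text = (
            resources.files("iaq").joinpath("data/reference_bundle.json").read_text()
        )
        doc = json.loads(text)
    elif isinstance(source, Mapping):
        doc = source
    else:
        doc = json.loads(Path(source).read_text())
    return _build_bundle(doc)


_DEFAULT: ReferenceBundle | None = None


def default_bundle() -> ReferenceBundle:
    """The package's shipped reference bundle (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_reference_bundle()
    return _DEFAULT
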