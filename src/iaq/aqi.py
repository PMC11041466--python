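"""Weighted-mean indoor AQI, gauge categories, dashboard labels, tips.

The indoor AQI is the weighted mean of the current pollutant readings

    AQI = sum(W_i * P_i) / sum(W_i)

over whichever of the six lifestyle pollutants (PM2.5, tVOC, CO2, O3, CO,
PM10) are available; missing pollutants simply drop out of both sums.  Note
the readings enter in each pollutant's own canonical unit (µg/m³, ppm, ppb)
without conversion — the index definition operates on raw scale values, so
the result is a unitless convex combination of the readings, not a
concentration.

Readings fed to :func:`compute_aqi` are intended to be 1-hour trailing means
of each stream (see :mod:`iaq.exposure`); a partial first hour uses whatever
samples exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .reference_tables import AQI_POLLUTANTS
from .weightage import default_weights

__all__ = [
    "AqiResult",
    "DashboardLabel",
    "Recommendation",
    "compute_aqi",
    "aqi_category",
    "dashboard_label",
    "recommendation_for",
    "DEFAULT_DASHBOARD_EDGES",
    "GAUGE_BANDS",
]

#: US AQI gauge cut points; boundary values map to the lower (healthier) band.
GAUGE_BANDS: tuple[tuple[float, str], ...] = (
    (50, "Good"),
    (100, "Moderate"),
    (150, "Unhealthy for Sensitive Groups"),
    (200, "Unhealthy"),
    (300, "Very Unhealthy"),
    (float("inf"), "Hazardous"),
)

#: Default 4-way dashboard edges (GOOD <= e0 < MODERATE <= e1 < POOR <= e2 < BAD),
#: in each pollutant's canonical unit.  tVOC and CO2 edges come from the
#: published safe/moderate/extreme ranges (tVOC safe 0-200 ppb, moderate
#: 220-660 ppb, extreme above 2200 ppb; CO2 safe 250-1000 ppm); PM2.5 GOOD
#: tops at the EPA 24-h limit of 35 µg/m³; the remaining edges reuse IAQI
#: breakpoint levels.  All overridable per deployment.
DEFAULT_DASHBOARD_EDGES: dict[str, tuple[float, float, float]] = {
    "tvoc": (200, 660, 2200),  # ppb
    "co2": (1000, 2000, 5000),  # ppm
    "pm25": (35, 75, 150),  # µg/m³
    "pm10": (50, 150, 350),  # µg/m³
    "co": (2, 9, 30.4),  # ppm
    "o3": (160, 200, 400),  # µg/m³
}

_DASH_LABELS = ("GOOD", "MODERATE", "POOR", "BAD")


@dataclass(frozen=True)
class AqiResult:
    value: float
    category: str
    contributions: dict[str, tuple[float, float, float]]  # P_i, W_i, W_i*P_i
    pollutants_used: tuple[str, ...]


@dataclass(frozen=True)
class DashboardLabel:
    pollutant: str
    reading: float
    label: str
    thresholds_used: tuple[float, float, float]


@dataclass(frozen=True)
class Recommendation:
    pollutant: str
    thresholds: str
    advice: tuple[str, ...]


def compute_aqi(
    readings: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> AqiResult:
    """Weighted-mean AQI over the supplied pollutant readings.

    ``readings`` maps pollutant id to the current (typically 1-hour mean)
    value in the pollutant's canonical unit.  ``weights`` defaults to the
    derived final weightages of the six AQI pollutants.
    """
    if not readings:
        raise ValueError("readings must be nonempty")
    weights = weights if weights is not None else default_weights()
    num = 0.0
    den = 0.0
    contributions: dict[str, tuple[float, float, float]] = {}
    for pid, p in readings.items():
        if p < 0:
            raise ValueError(f"negative reading for {pid}: {p}")
        try:
            w = weights[pid]
        except KeyError:
            raise LookupError(f"no weight for pollutant {pid!r}") from None
        num += w * p
        den += w
        contributions[pid] = (p, w, w * p)
    value = num / den
    return AqiResult(
        value=value,
        category=aqi_category(value),
        contributions=contributions,
        pollutants_used=tuple(readings),
    )


def aqi_category(value: float) -> str:
    """US-gauge category for an AQI value; boundaries belong to the lower band."""
    if value < 0:
        raise ValueError("AQI value must be non-negative")
    for upper, label in GAUGE_BANDS:
        if value <= upper:
            return label
    raise AssertionError("unreachable")


def dashboard_label(
    pollutant: str,
    reading: float,
    edges: Mapping[str, tuple[float, float, float]] | None = None,
) -> DashboardLabel:
    """4-level GOOD/MODERATE/POOR/BAD label for a dashboard tile.

    Boundary values map to the lower (healthier) label.
    """
    edges = edges if edges is not None else DEFAULT_DASHBOARD_EDGES
    try:
        e = edges[pollutant]
    except KeyError:
        raise LookupError(f"no dashboard thresholds configured for {pollutant!r}") from None
    if reading < 0:
        raise ValueError("reading must be non-negative")
    for bound, label in zip(e, _DASH_LABELS):
        if reading <= bound:
            return DashboardLabel(pollutant, reading, label, tuple(e))
    return DashboardLabel(pollutant, reading, "BAD", tuple(e))


_RECOMMENDATIONS: dict[str, Recommendation] = {
    "co2": Recommendation(
        "co2",
        "Safe 250-1000 ppm for ventilated indoor spaces; above 1000 ppm expect "
        "drowsiness, headaches and reduced concentration.",
        (
            "Improve ventilation and air circulation: open windows and doors.",
            "Add or run a fan in rooms heated without air circulation.",
            "Air out closed rooms regularly in winter.",
        ),
    ),
    "pm25": Recommendation(
        "pm25",
        "EPA 24-hour exposure limit 35 µg/m³ (annual 12 µg/m³).",
        (
            "Activate the kitchen exhaust fan while cooking.",
            "Open windows for cross-ventilation after cooking.",
            "Consider a HEPA air purifier for persistent elevations.",
        ),
    ),
    "pm10": Recommendation(
        "pm10",
        "Keep the 24-hour mean below 50 µg/m³ (IAQI 50 breakpoint).",
        (
            "Dust and vacuum with a filtered vacuum regularly.",
            "Keep windows closed during high outdoor dust or pollen episodes.",
        ),
    ),
    "tvoc": Recommendation(
        "tvoc",
        "Safe 0-200 ppb; moderate 220-660 ppb; above 2200 ppb is extremely "
        "unhealthy.",
        (
            "Ventilate while cleaning, cooking or using cosmetics and paints.",
            "Prefer low-VOC cleaning products and paints.",
            "Store solvents and fuels outside living areas.",
        ),
    ),
    "co": Recommendation(
        "co",
        "Keep the 1-hour mean below 5 (IAQI 50 breakpoint); any sustained rise "
        "indicates incomplete combustion.",
        (
            "Service fuel-burning appliances and never run engines indoors.",
            "Install a CO alarm near sleeping areas.",
        ),
    ),
    "o3": Recommendation(
        "o3",
        "Keep the 1-hour mean below 160 (IAQI 50 breakpoint); VOC spikes in "
        "sunlight drive ground-level ozone.",
        (
            "Limit VOC-emitting activities during strong sunlight.",
            "Ventilate when outdoor ozone is low (early morning, night).",
        ),
    ),
    "ng": Recommendation(
        "ng",
        "Any sustained reading above baseline may indicate a leak.",
        (
            "If a leak is suspected: ventilate, avoid ignition sources and "
            "contact the gas utility immediately.",
        ),
    ),
}


def recommendation_for(pollutant: str) -> Recommendation:
    """Static threshold text and mitigation advice for a pollutant tile."""
    try:
        return _RECOMMENDATIONS[pollutant]
    except KeyError:
        raise LookupError(f"no recommendation entry for {pollutant!r}") from None
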