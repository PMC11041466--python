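"""Low-cost sensor calibration: burn-in gating, OLS correction, accuracy.

Metal-oxide gas sensors ship with channel-specific gain and offset error.
The correction procedure is:

1. **Burn-in** — a channel must run powered in clean air for 48 hours before
   its readings count for calibration; earlier readings are flagged, never
   deleted.
2. **Paired accumulation** — raw readings are paired daily with a co-located
   reference instrument (a pre-calibrated consumer device, or the nearest
   outdoor station) over a 15-day window.
3. **Fit** — ordinary least squares predicting reference from raw,
   ``reference ≈ slope·raw + intercept``, one independent model per channel.
   The fit is the deterministic closed form; no stochastic optimiser.
4. **Apply** — corrected = slope·raw + intercept, with negative corrected
   values clamped to zero and flagged.
5. **Recalibrate** — a model is due for refresh 90 days (3 months) after it
   was fitted, which comfortably outpaces the slow drift of these sensors.

Accuracy is scored as mean relative agreement,
``100·(1 − mean(|corrected − reference| / reference))``, an interpretation of
"percent accuracy against the reference" since no formula is standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "BurnInState",
    "BURN_IN_HOURS",
    "RECALIBRATION_DAYS",
    "ACCUMULATION_DAYS",
    "check_burn_in",
    "fit_calibration",
    "apply_calibration",
    "accuracy_score",
    "recalibration_due",
]

BURN_IN_HOURS = 48
RECALIBRATION_DAYS = 90
#: Default paired-accumulation window for the initial fit, days.
ACCUMULATION_DAYS = 15


@dataclass(frozen=True)
class CalibrationPair:
    timestamp: datetime
    raw: float
    reference: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.raw) and np.isfinite(self.reference)):
            raise ValueError("raw and reference must be finite")
        if self.reference < 0:
            raise ValueError("reference must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    channel: str
    slope: float
    intercept: float
    n_pairs: int
    fit_window: tuple[datetime, datetime]
    r_squared: float
    fitted_on: datetime

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_pairs": self.n_pairs,
            "fit_window": [t.isoformat() for t in self.fit_window],
            "r_squared": self.r_squared,
            "fitted_on": self.fitted_on.isoformat(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibrationModel":
        return cls(
            channel=doc["channel"],
            slope=doc["slope"],
            intercept=doc["intercept"],
            n_pairs=doc["n_pairs"],
            fit_window=tuple(datetime.fromisoformat(t) for t in doc["fit_window"]),
            r_squared=doc["r_squared"],
            fitted_on=datetime.fromisoformat(doc["fitted_on"]),
        )


@dataclass
class BurnInState:
    channel: str
    powered_since: datetime
    burned_in: bool = False


def check_burn_in(state: BurnInState, now: datetime) -> bool:
    """True once the channel has been powered for at least 48 hours."""
    if state.powered_since > now:
        raise ValueError("powered_since is in the future")
    done = now - state.powered_since >= timedelta(hours=BURN_IN_HOURS)
    state.burned_in = done
    return done


def fit_calibration(
    pairs: Sequence[CalibrationPair], channel: str = "", fitted_on: datetime | None = None
) -> CalibrationModel:
    """Least-squares line predicting the reference value from the raw reading."""
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 calibration pairs, got {len(pairs)}")
    raw = np.array([p.raw for p in pairs], dtype=float)
    ref = np.array([p.reference for p in pairs], dtype=float)
    if np.ptp(raw) == 0:
        raise ValueError("degenerate design: raw values are constant")
    fit = stats.linregress(raw, ref)
    times = [p.timestamp for p in pairs]
    return CalibrationModel(
        channel=channel,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=len(pairs),
        fit_window=(min(times), max(times)),
        r_squared=float(fit.rvalue) ** 2,
        fitted_on=fitted_on or max(times),
    )


def apply_calibration(
    model: CalibrationModel, raw_series: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Map readings through the corrective line.

    Returns ``(corrected, clamped)``: corrected values with negatives clamped
    to zero, and a boolean flag array marking the clamped positions.
    """
    raw = np.asarray(raw_series, dtype=float)
    corrected = model.slope * raw + model.intercept
    clamped = corrected < 0
    return np.where(clamped, 0.0, corrected), clamped


def accuracy_score(
    corrected: Sequence[float], reference: Sequence[float]
) -> float:
    """Percent agreement: ``100·(1 − mean(|corrected − reference|/reference))``.

    Zero reference values carry an undefined relative error and are excluded;
    the score is floored at 0.  Raises when the series lengths differ or
    every reference value is zero.
    """
    corrected = np.asarray(corrected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if corrected.shape != reference.shape:
        raise ValueError("corrected and reference must have equal length")
    keep = reference > 0
    if not keep.any():
        raise ValueError("all reference values are zero; accuracy undefined")
    rel = np.abs(corrected[keep] - reference[keep]) / reference[keep]
    return max(0.0, 100.0 * (1.0 - float(rel.mean())))


def recalibration_due(model: CalibrationModel, now: datetime) -> bool:
    """True once the model is 90 days (3 months) old."""
    return now - model.fitted_on >= timedelta(days=RECALIBRATION_DAYS)
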