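"""Pollutant weightage derivation.

Each pollutant's importance in the weighted-mean indoor AQI is derived from
its IAQI scale: at every index level r the per-level weight is the fractional
contribution

    w_r = IAQI_r / PCM_r

where PCM_r is the pollutant's concentration threshold mean at that level,
and the final weight W_p is the unweighted arithmetic mean of the per-level
weights over whatever levels the pollutant's scale defines (tVOC has 4,
CO2 has 6, the others 7; level 0 is not part of the published worksheets and
contributes no term).
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference_tables import AQI_POLLUTANTS, ReferenceBundle, default_bundle

__all__ = [
    "LevelWeightage",
    "WeightageTable",
    "level_weightage",
    "final_weightage",
    "default_weights",
]


@dataclass(frozen=True)
class LevelWeightage:
    pollutant: str
    iaqi_level: float
    representation: float
    weight: float


@dataclass(frozen=True)
class WeightageTable:
    pollutant: str
    levels: tuple[LevelWeightage, ...]
    final_weight: float

    def to_records(self) -> list[dict]:
        rows = [
            {
                "pollutant": lw.pollutant,
                "iaqi_level": lw.iaqi_level,
                "representation": lw.representation,
                "weight": lw.weight,
            }
            for lw in self.levels
        ]
        rows.append(
            {
                "pollutant": self.pollutant,
                "iaqi_level": None,
                "representation": None,
                "weight": self.final_weight,
            }
        )
        return rows


def level_weightage(iaqi_level: float, representation: float) -> float:
    """Fractional contribution of one IAQI level: ``iaqi_level / representation``."""
    if representation <= 0:
        raise ValueError("representation must be > 0")
    if iaqi_level < 0:
        raise ValueError("iaqi_level must be >= 0")
    return iaqi_level / representation


def final_weightage(
    pollutant: str, bundle: ReferenceBundle | None = None
) -> WeightageTable:
    """Per-level weights and their arithmetic mean for one pollutant."""
    bundle = bundle or default_bundle()
    table = bundle.representations.get(pollutant)
    if table is None or not table.levels:
        raise LookupError(f"no representation levels for {pollutant!r}")
    levels = tuple(
        LevelWeightage(pollutant, lvl, rep, level_weightage(lvl, rep))
        for lvl, rep in table.levels
    )
    final = sum(lw.weight for lw in levels) / len(levels)
    return WeightageTable(pollutant, levels, final)


def default_weights(bundle: ReferenceBundle | None = None) -> dict[str, float]:
    """Final weights W_i for the six AQI pollutants, keyed by pollutant id."""
    bundle = bundle or default_bundle()
    return {p: final_weightage(p, bundle).final_weight for p in AQI_POLLUTANTS}
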