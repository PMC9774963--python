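"""Four-stage ecological periodization by reconstructed size, stage
durations under linear growth, and population biomass partitioning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "StageDefinition", "GrowthScenario", "STAGES", "ALTERNATIVE_SCHEMES",
    "classify", "stage_label", "stage_duration", "biomass_partition",
]


@dataclass(frozen=True)
class StageDefinition:
    stage_id: int
    ml_low_mm: float       # half-open [low, high)
    ml_high_mm: float
    requires_gelatinous: bool
    habitat: str
    diet: str
    mass_low_g: float | None = None
    mass_high_g: float | None = None


#: The size-based periodization.  Boundary convention is [low, high): 20 mm
#: falls in stage 2 and 50 mm in stage 3.  Stage 4 overrides by the
#: gelatinous flag for ML >= 200 mm.
STAGES = (
    StageDefinition(1, 0.0, 20.0, False, "epipelagic",
                    "mostly crustaceans, especially copepods", None, 0.4),
    StageDefinition(2, 20.0, 50.0, False, "epipelagic, occasionally deeper",
                    "larger crustaceans, fish, cephalopods", 0.7, 5.8),
    StageDefinition(3, 50.0, float("inf"), False, "meso- and bathypelagic",
                    "mainly fish and cephalopods, cannibalism", 6.3, None),
    StageDefinition(4, 200.0, float("inf"), True, "bathypelagic",
                    "non-feeding gelatinous females", 208.7, None),
)

#: Earlier periodizations shipped for labelled comparison output only.
ALTERNATIVE_SCHEMES = {
    "maturity_stage": ["0", "I", "II", "III", "IV", "V1", "V2", "V3", "VI"],
    "classical_ecology": [
        "epipelagic paralarvae (3.5-15 mm)",
        "epipelagic (15-60 mm)",
        "mesopelagic (60-130/150 mm)",
        "bathypelagic (> 130/150 mm)",
        "bathypelagic gelatinous (> 200 mm)",
    ],
}


def classify(ml_mm: float, gelatinous: bool = False) -> int:
    """Stage id (1-4) for a mantle length; gelatinous >= 200 mm -> 4."""
    if ml_mm <= 0:
        raise ValueError("mantle length must be positive")
    if gelatinous:
        if ml_mm >= 200.0:
            return 4
        warnings.warn(
            f"gelatinous individual with ML {ml_mm:g} mm < 200 mm: "
            "stage 4 is defined only above 200 mm, classifying by size"
        )
    if ml_mm < 20.0:
        return 1
    if ml_mm < 50.0:
        return 2
    return 3


def stage_label(stage_id: int) -> str:
    for s in STAGES:
        if s.stage_id == stage_id:
            return f"stage {s.stage_id}: {s.habitat}; {s.diet}"
    raise ValueError(f"unknown stage id {stage_id}")


@dataclass(frozen=True)
class GrowthScenario:
    growth_rate_mm_per_day: float
    hatchling_ml_mm: float = 3.5
    days_per_month: float = 30.44

    def __post_init__(self) -> None:
        if min(self.growth_rate_mm_per_day, self.hatchling_ml_mm, self.days_per_month) <= 0:
            raise ValueError("all growth-scenario fields must be positive")


def stage_duration(from_ml: float, to_ml: float, scenario: GrowthScenario) -> float:
    """Months spent between two mantle lengths under linear growth."""
    if to_ml < from_ml:
        raise ValueError("to_ml must be >= from_ml")
    days = (to_ml - from_ml) / scenario.growth_rate_mm_per_day
    return days / scenario.days_per_month


def biomass_partition(
    components: list[tuple[str, float]],
    gelatinous: tuple[float, float, str] | None = None,
) -> dict:
    """Percent-of-total partition of population biomass components.

    ``components`` are (label, biomass Mt) pairs; percentages are rounded
    to integers for the report (raw fractions kept alongside).  When
    ``gelatinous = (survival_fraction, sex_ratio, base_label)`` is given,
    gelatinous biomass = base * sex_ratio * survival is reported separately
    and does not enter the main partition.
    """
    if any(b < 0 for _, b in components):
        raise ValueError("biomasses must be non-negative")
    total = sum(b for _, b in components)
    if total == 0:
        raise ValueError("zero total biomass")
    report = {
        label: {
            "biomass_mt": b,
            "percent": b / total * 100.0,
            "percent_rounded": round(b / total * 100.0),
        }
        for label, b in components
    }
    out = {"total_mt": total, "components": report}
    if gelatinous is not None:
        survival, sex_ratio, base_label = gelatinous
        if not (0 <= survival <= 1 and 0 <= sex_ratio <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        base = dict(components)[base_label]
        out["gelatinous_mt"] = base * sex_ratio * survival
    return out
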