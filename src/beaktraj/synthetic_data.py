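"""Synthetic populations, known-truth diet mixtures, and the packaged
per-individual summary fixture used by the acceptance suite.

The trajectory generator follows the structure the analysis assumes: a
piecewise-linear population curve per isotope (steep early increments that
flatten later), an individual random intercept, per-subsection measurement
noise, and completely-at-random (optionally block) missing cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import (
    BeakSubsection, IndividualTrajectory, IsotopeMeasurement, PopulationSample,
)
from .mixing_model import SourceSpec, TEFSpec


@dataclass
class IsotopeCurve:
    """Population mean value per subsection: linear ramp then plateau drift."""

    start_mean: float
    steep_increment: float
    flat_increment: float
    steep_from: int          # first subsection of the steep phase (1-based)
    steep_to: int            # last subsection of the steep phase

    def mean_at(self, subsection: int) -> float:
        v = self.start_mean
        for s in range(2, subsection + 1):
            if self.steep_from < s <= self.steep_to:
                v += self.steep_increment
            elif s > self.steep_to:
                v += self.flat_increment
        return v


@dataclass
class TrajectorySimParams:
    n_individuals: int = 14
    subsection_count_range: tuple[int, int] = (11, 17)
    d13c_curve: IsotopeCurve = field(default_factory=lambda: IsotopeCurve(
        start_mean=-20.5, steep_increment=0.29, flat_increment=0.01,
        steep_from=1, steep_to=5))
    d15n_curve: IsotopeCurve = field(default_factory=lambda: IsotopeCurve(
        start_mean=9.1, steep_increment=0.89, flat_increment=0.08,
        steep_from=2, steep_to=7))
    # defaults put d15N in the generalist regime (within-trajectory ramp
    # dominates) while d13C individuals straddle the specialist boundary
    between_individual_sd_d13c: float = 0.4
    between_individual_sd_d15n: float = 0.3
    measurement_sd: float = 0.2
    missing_probability: float = 0.0
    missing_probability_d13c: float | None = None
    missing_probability_d15n: float | None = None
    block_missing: bool = False
    random_slope_sd: float = 0.0
    sex_ratio_female: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.measurement_sd < 0 or min(
            self.between_individual_sd_d13c, self.between_individual_sd_d15n
        ) < 0:
            raise ValueError("SDs must be non-negative")
        for p in (self.missing_probability, self.sex_ratio_female):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _mask_indices(rng, n, prob, block):
    if prob <= 0:
        return np.zeros(n, dtype=bool)
    if prob >= 1:
        return np.ones(n, dtype=bool)
    if block:
        # one contiguous failed run whose expected length matches prob * n
        length = min(n, max(1, int(round(prob * n))))
        start = int(rng.integers(0, n - length + 1))
        mask = np.zeros(n, dtype=bool)
        mask[start:start + length] = True
        return mask
    return rng.random(n) < prob


def simulate_population(params: TrajectorySimParams) -> PopulationSample:
    """Individual = population curve + random intercept + per-cell noise."""
    if params.n_individuals < 2:
        raise ValueError("need >= 2 individuals for population statistics")
    rng = np.random.default_rng(params.seed)
    lo, hi = params.subsection_count_range
    p13 = params.missing_probability_d13c
    p15 = params.missing_probability_d15n
    p13 = params.missing_probability if p13 is None else p13
    p15 = params.missing_probability if p15 is None else p15

    trajectories = []
    for i in range(params.n_individuals):
        n_sub = int(rng.integers(lo, hi + 1))
        icpt13 = rng.normal(0.0, params.between_individual_sd_d13c)
        icpt15 = rng.normal(0.0, params.between_individual_sd_d15n)
        slope13 = rng.normal(0.0, params.random_slope_sd) if params.random_slope_sd else 0.0
        slope15 = rng.normal(0.0, params.random_slope_sd) if params.random_slope_sd else 0.0
        m13 = _mask_indices(rng, n_sub, p13, params.block_missing)
        m15 = _mask_indices(rng, n_sub, p15, params.block_missing)
        sex = "female" if rng.random() < params.sex_ratio_female else "male"
        subs = []
        for s in range(1, n_sub + 1):
            v13 = (params.d13c_curve.mean_at(s) + icpt13 + slope13 * (s - 1)
                   + rng.normal(0.0, params.measurement_sd))
            v15 = (params.d15n_curve.mean_at(s) + icpt15 + slope15 * (s - 1)
                   + rng.normal(0.0, params.measurement_sd))
            subs.append(BeakSubsection(
                index=s,
                measurement=IsotopeMeasurement(
                    delta13c=math.nan if m13[s - 1] else v13,
                    delta15n=math.nan if m15[s - 1] else v15,
                ),
            ))
        trajectories.append(IndividualTrajectory(
            individual_id=f"S{i + 1}", subsections=subs, sex=sex,
            mantle_length_mm=200.0 + 10.0 * i,
        ))
    return PopulationSample(trajectories=trajectories)


# ---------------------------------------------------------------------------
# Known-truth diet mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureTruth:
    proportions: np.ndarray
    n_consumers: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not math.isclose(float(self.proportions.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("true proportions must sum to 1")


def simulate_consumers(
    truth: MixtureTruth,
    sources: list[SourceSpec],
    tef: TEFSpec | None = None,
    resid_sd: float = 0.0,
) -> np.ndarray:
    """Consumers drawn from the mixing model's own likelihood at the true
    proportions; deterministic under a fixed seed."""
    tef = tef or TEFSpec()
    rng = np.random.default_rng(truth.seed)
    p = truth.proportions
    mu_s = np.array([[s.mean_d13c, s.mean_d15n] for s in sources])
    var_s = np.array([[s.sd_d13c ** 2, s.sd_d15n ** 2] for s in sources])
    mu_tef = np.array([tef.mean_d13c, tef.mean_d15n])
    var_tef = np.array([tef.sd_d13c ** 2, tef.sd_d15n ** 2])
    mean = p @ (mu_s + mu_tef)
    var = (p ** 2) @ (var_s + var_tef) + resid_sd ** 2
    return mean + rng.standard_normal((truth.n_consumers, 2)) * np.sqrt(var)


# ---------------------------------------------------------------------------
# Packaged per-individual summary fixture
# ---------------------------------------------------------------------------

# Printed per-individual summary numbers: one row per (individual, character)
# with character in {d13c, d15n, tl}.  Fields: sex, adult ML (mm),
# gelatinous flag, n analysed / n available, min, max, mean, SE,
# specialization s (None where not applicable/available), subsection of the
# minimum / maximum, range min-to-max, range newest-to-oldest.
_TABLE1_ROWS = [
    # id,  sex,      ml, gel,  char,  na, nv,  min,   max,   mean,  se,    s,    amin, amax, rng_mm, rng_fl
    ("F1", "female", 214, False, "d13c", 13, 13, -20.5, -18.6, -19.2, 0.19, 0.78, 1, 7, 1.87, 1.82),
    ("F1", "female", 214, False, "d15n", 13, 13, 7.9, 13.5, 11.8, 0.54, 0.97, 2, 10, 4.60, 4.08),
    ("F1", "female", 214, False, "tl", 13, 13, 3.0, 4.5, 4.0, 0.14, None, 2, 10, 1.47, 1.07),
    ("F2", "female", 215, False, "d13c", 13, 13, -20.5, -19.4, -19.9, 0.09, 0.45, 3, 8, 1.04, 0.71),
    ("F2", "female", 215, False, "d15n", 13, 13, 8.6, 13.5, 11.4, 0.49, 0.96, 1, 8, 4.90, 3.58),
    ("F2", "female", 215, False, "tl", 13, 13, 3.2, 4.5, 3.9, 0.13, None, 1, 8, 1.29, 0.94),
    ("F3", "female", 238, False, "d13c", 11, 15, -20.5, -18.9, -19.6, 0.17, 0.71, 1, 14, 1.60, 1.42),
    ("F3", "female", 238, False, "d15n", 12, 15, 10.3, 16.7, 13.9, 0.63, 0.97, 6, 13, 6.42, 4.30),
    ("F3", "female", 238, False, "tl", 12, 15, 3.6, 5.3, 4.6, 0.17, None, 6, 13, 1.69, 1.13),
    ("F4", "female", 249, False, "d13c", 6, 14, -19.4, -18.6, -19.1, 0.12, 0.40, 4, 5, 0.75, 0.06),
    ("F4", "female", 249, False, "d15n", 10, 14, 6.4, 15.5, 11.9, 0.82, 0.98, 2, 4, 9.09, 8.85),
    ("F4", "female", 249, False, "tl", 10, 14, 3.0, 5.4, 4.5, 0.22, None, 2, 4, 2.39, 2.33),
    ("F5", "female", 257, False, "d13c", 9, 13, -19.8, -19.0, -19.3, 0.09, 0.37, 4, 6, 0.76, 0.61),
    ("F5", "female", 257, False, "d15n", 10, 13, 13.7, 16.3, 15.6, 0.25, 0.83, 4, 11, 2.62, 1.61),
    ("F5", "female", 257, False, "tl", 10, 13, 4.5, 5.2, 5.0, 0.07, None, 4, 11, 0.69, 0.42),
    ("F6", "female", 230, True, "d13c", 15, 15, -20.2, -18.5, -19.2, 0.11, 0.57, 1, 15, 1.71, 1.71),
    ("F6", "female", 230, True, "d15n", 15, 15, 11.2, 16.7, 15.0, 0.45, 0.96, 1, 15, 5.58, 5.58),
    ("F6", "female", 230, True, "tl", 15, 15, 3.6, 5.1, 4.7, 0.12, None, 1, 15, 1.47, 1.47),
    ("M1", "male", 216, False, "d13c", 9, 12, -20.1, -18.5, -19.0, 0.17, 0.66, 1, 4, 1.60, 1.05),
    ("M1", "male", 216, False, "d15n", 9, 12, 8.9, 14.4, 12.5, 0.65, 0.97, 1, 10, 5.41, 4.52),
    ("M1", "male", 216, False, "tl", 9, 12, 3.3, 4.7, 4.2, 0.17, None, 1, 10, 1.42, 1.19),
    ("M2", "male", 221, False, "d13c", 11, 11, -21.2, -19.3, -19.9, 0.20, 0.77, 1, 5, 1.90, 1.59),
    ("M2", "male", 221, False, "d15n", 11, 11, 6.1, 12.4, 9.9, 0.75, 0.98, 1, 10, 6.23, 5.86),
    ("M2", "male", 221, False, "tl", 11, 11, 3.0, 4.6, 4.0, 0.20, None, 1, 10, 1.64, 1.54),
    ("M3", "male", 269, False, "d13c", 14, 14, -21.0, -19.4, -20.0, 0.15, 0.70, 1, 8, 1.57, 1.20),
    ("M3", "male", 269, False, "d15n", 14, 14, 9.5, 15.4, 13.1, 0.57, 0.97, 2, 10, 5.94, 4.29),
    ("M3", "male", 269, False, "tl", 14, 14, 3.8, 5.3, 4.7, 0.15, None, 2, 10, 1.56, 1.13),
    ("M4", "male", 285, False, "d13c", 15, 16, -20.3, -18.2, -19.0, 0.16, 0.74, 1, 12, 2.18, 1.02),
    ("M4", "male", 285, False, "d15n", 15, 16, 5.6, 11.5, 9.6, 0.53, 0.97, 1, 11, 5.97, 4.51),
    ("M4", "male", 285, False, "tl", 15, 16, 3.0, 4.6, 4.1, 0.14, None, 1, 11, 1.57, 1.19),
    ("M5", "male", 252, False, "d13c", 14, 14, -19.6, -18.9, -19.2, 0.05, 0.21, 3, 6, 0.72, 0.11),
    ("M5", "male", 252, False, "d15n", 14, 14, 6.4, 12.3, 10.3, 0.49, 0.96, 3, 10, 5.95, 1.75),
    ("M5", "male", 252, False, "tl", 14, 14, 3.0, 4.6, 4.1, 0.13, None, 3, 10, 1.56, 0.46),
    ("M6", "male", 284, False, "d13c", 15, 15, -20.8, -19.2, -19.7, 0.12, 0.62, 1, 14, 1.55, 1.11),
    ("M6", "male", 284, False, "d15n", 15, 15, 11.1, 16.6, 14.5, 0.43, 0.96, 1, 13, 5.49, 3.18),
    ("M6", "male", 284, False, "tl", 15, 15, 3.8, 5.3, 4.7, 0.11, None, 1, 13, 1.45, 0.84),
    ("M7", "male", 298, False, "d13c", 4, 17, -19.5, -19.1, -19.2, 0.08, None, None, None, None, None),
    ("M7", "male", 298, False, "d15n", 13, 17, 10.3, 15.4, 13.8, 0.47, 0.96, 3, 9, 5.09, 4.27),
    ("M7", "male", 298, False, "tl", 13, 17, 4.1, 5.4, 5.0, 0.12, None, 3, 9, 1.34, 1.12),
    ("M8", "male", 325, False, "d13c", 12, 17, -20.7, -19.3, -19.7, 0.11, 0.51, 1, 6, 1.43, 0.80),
    ("M8", "male", 325, False, "d15n", 14, 17, 10.7, 15.1, 13.5, 0.42, 0.95, 2, 7, 4.41, 2.67),
    ("M8", "male", 325, False, "tl", 14, 17, 3.7, 4.9, 4.5, 0.11, None, 2, 7, 1.16, 0.70),
]

_TABLE1_COLUMNS = [
    "individual_id", "sex", "ml_mm", "gelatinous", "character",
    "n_analysed", "n_available", "min_value", "max_value", "mean", "se",
    "s", "argmin_subsection", "argmax_subsection",
    "range_min_to_max", "range_first_to_last",
]


def make_fixture_table1() -> pd.DataFrame:
    """The printed per-individual summary table as a tidy DataFrame.

    One row per (individual, character); the M7 carbon row has too few
    analysed subsections for ranges/specialization and carries NaN there.
    Known transcription caveat: the F1 nitrogen min/max (7.9-13.5) are
    inconsistent with the printed min-to-max range (4.60); both are kept
    verbatim, and consumers should prefer the range columns.
    """
    df = pd.DataFrame(_TABLE1_ROWS, columns=_TABLE1_COLUMNS)
    return df


def fixture_checksum() -> int:
    """Stable checksum over the fixture's numeric content (transcription guard)."""
    import zlib

    df = make_fixture_table1()
    payload = df.to_csv(index=False).encode()
    return zlib.crc32(payload)
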