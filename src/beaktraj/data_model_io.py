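"""Domain types and tidy CSV input/output for beak-subsection isotope data.

The canonical on-disk format is a tidy long CSV: one row per
(individual, subsection) pair, with blank cells for measurements that
were not (successfully) analysed.  Wide formats are deliberately not
accepted because they cannot represent per-isotope missingness
unambiguously.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("beaktraj")

VALID_SEXES = {"female", "male", "unknown"}

#: Advisory C:N mass-ratio band used by quality control (observed span of
#: well-behaved chitin samples).
DEFAULT_CN_BAND = (3.05, 3.86)

#: Replicate-precision threshold (per mil) above which QC emits an info flag.
DEFAULT_PRECISION_PERMIL = 0.2


class SchemaError(ValueError):
    """Raised when an input table violates the tidy-CSV contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IsotopeMeasurement:
    """A single dual-isotope measurement of one beak subsection.

    ``delta13c`` is per mil vs V-PDB, ``delta15n`` per mil vs AIR.
    A value of ``nan`` together with the matching missing flag marks an
    unanalysed isotope; the row itself is kept.
    """

    delta13c: float = math.nan
    delta15n: float = math.nan
    cn_ratio: float | None = None
    sample_mass_mg: float | None = None
    missing_d13c: bool = False
    missing_d15n: bool = False

    def __post_init__(self) -> None:
        if math.isnan(self.delta13c):
            self.missing_d13c = True
        if math.isnan(self.delta15n):
            self.missing_d15n = True
        if not self.missing_d13c and not math.isfinite(self.delta13c):
            raise ValueError("delta13c must be finite when not missing")
        if not self.missing_d15n and not math.isfinite(self.delta15n):
            raise ValueError("delta15n must be finite when not missing")
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio must be > 0, got {self.cn_ratio}")


@dataclass
class BeakSubsection:
    """One slice along the beak crest; index 1 is the rostrum tip (oldest)."""

    index: int
    crest_start_mm: float | None = None
    crest_end_mm: float | None = None
    measurement: IsotopeMeasurement | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("subsection index is 1-based")
        if self.crest_start_mm is not None and self.crest_end_mm is not None:
            if not (self.crest_end_mm > self.crest_start_mm >= 0):
                raise ValueError(
                    f"need crest_end > crest_start >= 0, got "
                    f"[{self.crest_start_mm}, {self.crest_end_mm}]"
                )


@dataclass
class IndividualTrajectory:
    """Ordered per-subsection measurements for one individual plus metadata."""

    individual_id: str
    subsections: list[BeakSubsection]
    sex: str = "unknown"
    maturity_stage: str | None = None
    mantle_length_mm: float | None = None
    body_mass_g: float | None = None
    gelatinous: bool = False
    station: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex code {self.sex!r}")
        if len(self.subsections) < 2:
            raise ValueError("a trajectory needs at least 2 subsections")
        idx = [s.index for s in self.subsections]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("subsection indices must be strictly increasing")
        if self.mantle_length_mm is not None and not self.mantle_length_mm > 0:
            raise ValueError("mantle_length_mm must be positive")

    def values(self, isotope: str, analysed_only: bool = True) -> list[tuple[int, float]]:
        """(subsection index, value) pairs for ``isotope`` in {'d13c', 'd15n'}."""
        out: list[tuple[int, float]] = []
        for sub in self.subsections:
            m = sub.measurement
            if m is None:
                continue
            if isotope == "d13c":
                missing, value = m.missing_d13c, m.delta13c
            elif isotope == "d15n":
                missing, value = m.missing_d15n, m.delta15n
            else:
                raise ValueError(f"unknown isotope {isotope!r}")
            if analysed_only and missing:
                continue
            out.append((sub.index, value))
        return out


@dataclass
class WholeBeakIndividual:
    """Population-level individual analysed as a single powdered beak."""

    individual_id: str
    measurement: IsotopeMeasurement
    sex: str = "unknown"
    mantle_length_mm: float | None = None


@dataclass
class PopulationSample:
    trajectories: list[IndividualTrajectory]
    whole_beak: list[WholeBeakIndividual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trajectories and not self.whole_beak:
            raise ValueError("population sample is empty")
        ids = [t.individual_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique within a population")

    def trajectory(self, individual_id: str) -> IndividualTrajectory:
        for t in self.trajectories:
            if t.individual_id == individual_id:
                return t
        raise KeyError(individual_id)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCFlag:
    level: str           # "warning" | "info"
    code: str
    message: str


def validate_measurement(
    m: IsotopeMeasurement,
    cn_band: tuple[float, float] = DEFAULT_CN_BAND,
    precision_permil: float = DEFAULT_PRECISION_PERMIL,
    replicate_sd: float | None = None,
) -> list[QCFlag]:
    """Advisory quality-control flags for one measurement.

    QC never rejects data: out-of-band C:N yields a warning, poor replicate
    precision an info flag, and absent optional fields are simply skipped.
    """
    flags: list[QCFlag] = []
    if m.cn_ratio is not None and not (cn_band[0] <= m.cn_ratio <= cn_band[1]):
        flags.append(QCFlag(
            "warning", "cn_out_of_band",
            f"C:N {m.cn_ratio:.2f} outside [{cn_band[0]}, {cn_band[1]}]",
        ))
    if replicate_sd is not None and replicate_sd > precision_permil:
        flags.append(QCFlag(
            "info", "replicate_sd",
            f"replicate SD {replicate_sd:.2f} exceeds {precision_permil}",
        ))
    return flags


# ---------------------------------------------------------------------------
# Subsection grid
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_subsection_grid(
    crest_length_mm: float,
    fine_mm: float = 1.0,
    coarse_mm: float = 2.0,
    rounding=_round_half_up,
) -> list[tuple[float, float]]:
    """Tile the crest with cutting boundaries: fine tiles over the anterior
    half, coarse tiles over the posterior half.

    "As close to N mm as possible" is realised by dividing each half into
    ``rounding(half / N)`` equal tiles (at least one), so widths are rescaled
    uniformly within each half and the tiles fit exactly.  The default
    rounding is round-half-up.
    """
    if crest_length_mm <= 0 or fine_mm <= 0 or coarse_mm <= 0:
        raise ValueError("lengths must be positive")
    half = crest_length_mm / 2.0
    n_fine = max(1, rounding(half / fine_mm))
    n_coarse = max(1, rounding(half / coarse_mm))
    bounds: list[tuple[float, float]] = []
    for i in range(n_fine):
        bounds.append((half * i / n_fine, half * (i + 1) / n_fine))
    for i in range(n_coarse):
        bounds.append((half + half * i / n_coarse, half + half * (i + 1) / n_coarse))
    # exact terminal boundary, immune to accumulation error
    bounds[-1] = (bounds[-1][0], crest_length_mm)
    return bounds


def attach_grid(traj: IndividualTrajectory, crest_length_mm: float, **kw) -> None:
    """Assign grid coordinates to a trajectory's subsections in place."""
    grid = build_subsection_grid(crest_length_mm, **kw)
    if len(grid) < len(traj.subsections):
        raise ValueError(
            f"grid has {len(grid)} tiles but trajectory has "
            f"{len(traj.subsections)} subsections"
        )
    for sub in traj.subsections:
        sub.crest_start_mm, sub.crest_end_mm = grid[sub.index - 1]


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("individual_id", "subsection", "d13c", "d15n")
OPTIONAL_COLUMNS = (
    "sex", "ml_mm", "mass_g", "maturity_stage", "gelatinous",
    "cn_ratio", "sample_mass_mg", "crest_start_mm", "crest_end_mm",
)


def _opt(row, col):
    if col not in row.index:
        return None
    v = row[col]
    if pd.isna(v):
        return None
    return v


def read_population(path: str | Path) -> PopulationSample:
    """Read a tidy long CSV into a :class:`PopulationSample`.

    Rows with blank isotope cells are kept with missing flags set, never
    dropped.  Duplicate (individual, subsection) pairs and unknown sex
    codes are hard errors.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    dup = df.duplicated(subset=["individual_id", "subsection"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["individual_id", "subsection"]].drop_duplicates()
        raise SchemaError(
            "duplicate (individual, subsection) pairs: "
            + ", ".join(f"({r.individual_id}, {r.subsection})" for r in pairs.itertuples())
        )
    if "sex" in df.columns:
        bad = df[~df["sex"].fillna("unknown").isin(VALID_SEXES)]
        if len(bad):
            raise SchemaError(
                "unknown sex codes in rows (0-based): "
                + ", ".join(f"{i}:{s!r}" for i, s in zip(bad.index, bad["sex"]))
            )

    trajectories = []
    for ind_id, g in df.groupby("individual_id", sort=False):
        g = g.sort_values("subsection")
        subsections = []
        for _, row in g.iterrows():
            m = IsotopeMeasurement(
                delta13c=float(row["d13c"]) if not pd.isna(row["d13c"]) else math.nan,
                delta15n=float(row["d15n"]) if not pd.isna(row["d15n"]) else math.nan,
                cn_ratio=_opt(row, "cn_ratio"),
                sample_mass_mg=_opt(row, "sample_mass_mg"),
            )
            subsections.append(BeakSubsection(
                index=int(row["subsection"]),
                crest_start_mm=_opt(row, "crest_start_mm"),
                crest_end_mm=_opt(row, "crest_end_mm"),
                measurement=m,
            ))
        first = g.iloc[0]
        sex = _opt(first, "sex") or "unknown"
        gel = bool(_opt(first, "gelatinous") or False)
        trajectories.append(IndividualTrajectory(
            individual_id=str(ind_id),
            subsections=subsections,
            sex=sex,
            maturity_stage=_opt(first, "maturity_stage"),
            mantle_length_mm=_opt(first, "ml_mm"),
            body_mass_g=_opt(first, "mass_g"),
            gelatinous=gel,
        ))
    return PopulationSample(trajectories=trajectories)


def write_population(pop: PopulationSample, path: str | Path) -> pd.DataFrame:
    """Write a population back to tidy CSV; returns the frame written."""
    rows = []
    for t in pop.trajectories:
        for sub in t.subsections:
            m = sub.measurement or IsotopeMeasurement()
            rows.append({
                "individual_id": t.individual_id,
                "subsection": sub.index,
                "d13c": math.nan if m.missing_d13c else m.delta13c,
                "d15n": math.nan if m.missing_d15n else m.delta15n,
                "sex": t.sex,
                "ml_mm": t.mantle_length_mm,
                "mass_g": t.body_mass_g,
                "maturity_stage": t.maturity_stage,
                "gelatinous": t.gelatinous,
                "cn_ratio": m.cn_ratio,
                "sample_mass_mg": m.sample_mass_mg,
                "crest_start_mm": sub.crest_start_mm,
                "crest_end_mm": sub.crest_end_mm,
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "allometry": {"preset": "west_greenland"},
    "trophic": {"baseline_d15n": 8.8, "baseline_tl": 2.0,
                "tef_per_level": 3.8, "beak_d15n_correction": 4.8},
    "mixing": {"n_iter": 20000, "burn_in": 5000, "thin": 5},
    "niche": {"alpha": 0.95, "n_draws": 2000},
    "simulate": {},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML or JSON config, layered over package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        user = yaml.safe_load(text)
    else:
        user = json.loads(text)
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def write_run_metadata(path: str | Path, **meta) -> None:
    payload = dict(meta)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
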