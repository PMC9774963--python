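"""Delta notation, trophic-level estimation, trajectory summaries,
individual specialization, and rank correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model_io import IndividualTrajectory, PopulationSample


@dataclass
class TrophicParams:
    """Parameters of the additive trophic-level equation.

    TL = baseline_tl + (d15n_beak + beak_d15n_correction - baseline_d15n) / tef_per_level

    The +4.8 per-mil beak correction converts beak chitin d15N to its
    muscle-tissue equivalent before the baseline comparison; the default
    enrichment of 3.8 per mil per level is the Arctic value (3.4 is the
    classical alternative).
    """

    baseline_d15n: float
    baseline_tl: float = 2.0
    tef_per_level: float = 3.8
    beak_d15n_correction: float = 4.8

    def __post_init__(self) -> None:
        if self.tef_per_level <= 0:
            raise ValueError("tef_per_level must be positive")
        if self.baseline_tl < 1:
            raise ValueError("baseline_tl must be >= 1")


def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil delta notation: (R_sample/R_standard - 1) * 1000."""
    if r_standard <= 0:
        raise ValueError("r_standard must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def estimate_tl(d15n_beak, params: TrophicParams):
    """Trophic level from a (raw) beak d15N value; vectorised and affine
    in d15n_beak with slope 1/tef_per_level."""
    d = np.asarray(d15n_beak, dtype=float)
    tl = params.baseline_tl + (
        d + params.beak_d15n_correction - params.baseline_d15n
    ) / params.tef_per_level
    return float(tl) if np.isscalar(d15n_beak) else tl


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

@dataclass
class IsotopeSummary:
    available: bool
    n_analysed: int
    n_available: int
    min_value: float = math.nan
    max_value: float = math.nan
    argmin_subsection: int | None = None
    argmax_subsection: int | None = None
    range_min_to_max: float = math.nan
    range_first_to_last: float = math.nan
    mean: float = math.nan
    se: float = math.nan


@dataclass
class TrajectorySummary:
    individual_id: str
    d13c: IsotopeSummary
    d15n: IsotopeSummary
    tl: IsotopeSummary | None = None
    specialization: dict = field(default_factory=dict)


def _summarize_values(pairs: list[tuple[int, float]], n_available: int) -> IsotopeSummary:
    if len(pairs) < 2:
        return IsotopeSummary(False, len(pairs), n_available)
    idx = [i for i, _ in pairs]
    vals = np.array([v for _, v in pairs], dtype=float)
    i_min = int(np.argmin(vals))
    i_max = int(np.argmax(vals))
    sd = float(np.std(vals, ddof=1))
    return IsotopeSummary(
        available=True,
        n_analysed=len(pairs),
        n_available=n_available,
        min_value=float(vals[i_min]),
        max_value=float(vals[i_max]),
        argmin_subsection=idx[i_min],
        argmax_subsection=idx[i_max],
        range_min_to_max=float(vals[i_max] - vals[i_min]),
        range_first_to_last=abs(float(vals[-1] - vals[0])),
        mean=float(vals.mean()),
        se=sd / math.sqrt(len(pairs)),
    )


def summarize_trajectory(
    traj: IndividualTrajectory, params: TrophicParams | None = None
) -> TrajectorySummary:
    """Per-isotope extremes, ranges, mean +- SE over analysed subsections.

    "Newest to oldest" is |value(last analysed) - value(first analysed)|;
    it equals the min-to-max range exactly when the extremes are terminal.
    The TL block mirrors the d15N block on the trophic-level scale.
    """
    n_avail = len(traj.subsections)
    s13 = _summarize_values(traj.values("d13c"), n_avail)
    s15 = _summarize_values(traj.values("d15n"), n_avail)
    tl = None
    if params is not None:
        tl_pairs = [(i, estimate_tl(v, params)) for i, v in traj.values("d15n")]
        tl = _summarize_values(tl_pairs, n_avail)
    return TrajectorySummary(traj.individual_id, d13c=s13, d15n=s15, tl=tl)


# ---------------------------------------------------------------------------
# Individual specialization
# ---------------------------------------------------------------------------

def specialization_index(
    traj: IndividualTrajectory,
    population: PopulationSample,
    isotope: str,
    ddof: int = 1,
) -> float:
    """Within/(among + within) variance ratio, in [0, 1].

    ``s`` is the variance of the individual's analysed subsection values
    divided by that same variance plus the variance of per-individual mean
    values across the population.  ``s`` < 0.5 marks an individual
    specialist; s -> 1 an extreme generalist.  ``ddof=1`` uses sample
    variances (default); ``ddof=0`` population-denominator variances.
    """
    own = [v for _, v in traj.values(isotope)]
    if len(own) < 2:
        raise ValueError("need >= 2 analysed values for the individual")
    means = []
    for t in population.trajectories:
        vals = [v for _, v in t.values(isotope)]
        if vals:
            means.append(float(np.mean(vals)))
    if len(means) < 2:
        raise ValueError("need >= 2 individuals with data in the population")
    v_within = float(np.var(own, ddof=ddof))
    v_among = float(np.var(means, ddof=ddof))
    total = v_among + v_within
    if total == 0:
        raise ValueError("zero total variance: specialization index undefined")
    return v_within / total


def is_specialist(s: float, threshold: float = 0.5) -> bool:
    return s < threshold


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties and t-approximation p.

    Pairs with either value missing (NaN) are dropped (pairwise deletion);
    at least 3 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for all-tied input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
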