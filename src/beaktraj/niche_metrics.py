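"""Isotopic-niche geometry in (d13C, TL) space.

Standard ellipse areas (SEA, small-sample corrected SEAc, Bayesian SEAb),
convex-hull area (TA), maximum-likelihood ellipse overlap, and posterior
probabilistic niche-region overlap between groups.

Caveat logged, not enforced: groups built from sequential subsections of
the same beaks are not independent samples.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .isotope_metrics import TrophicParams, estimate_tl

logger = logging.getLogger("beaktraj")

#: Overlap-fraction categories; only "large" is treated as significant.
OVERLAP_THRESHOLDS = {"none": (0.0, 0.29), "medium": (0.30, 0.60), "large": (0.61, 1.0)}

_ELLIPSE_VERTICES = 720  # polygonal approximation; relative area error ~1e-5


@dataclass
class NicheGroup:
    label: str
    points: np.ndarray  # (n, 2): x = d13C, y = TL (or d15N)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class NicheMetrics:
    sea: float
    seac: float
    ta_hull: float
    seab_draws: np.ndarray | None = None

    @property
    def seab_mean(self) -> float:
        return float(np.mean(self.seab_draws)) if self.seab_draws is not None else math.nan

    @property
    def seab_sd(self) -> float:
        return float(np.std(self.seab_draws, ddof=1)) if self.seab_draws is not None else math.nan


@dataclass
class OverlapResult:
    overlap_fraction: float

    @property
    def category(self) -> str:
        f = self.overlap_fraction
        if f <= 0.29:
            return "none"
        if f <= 0.60:
            return "medium"
        return "large"

    @property
    def significant(self) -> bool:
        return self.category == "large"


def build_niche_space(
    individuals, params: TrophicParams, label: str = ""
) -> NicheGroup:
    """Per-individual (d13C, d15N) points -> (d13C, TL) niche group.

    Each row is one individual's representative value (its whole-beak
    measurement or the mean of its subsection values); the y coordinate is
    transformed to trophic level, x is left unchanged.
    """
    pts = np.atleast_2d(np.asarray(individuals, dtype=float))
    if params is None:
        raise ValueError("a TrophicParams with a baseline is required")
    y = estimate_tl(pts[:, 1], params)
    return NicheGroup(label=label, points=np.column_stack([pts[:, 0], y]))


def group_means(trajectories, isotopes=("d13c", "d15n")) -> np.ndarray:
    """Mean isotopic value over all analysed subsections per individual."""
    rows = []
    for t in trajectories:
        rows.append([np.mean([v for _, v in t.values(iso)]) for iso in isotopes])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Ellipse machinery
# ---------------------------------------------------------------------------

def _sea_from_cov(cov: np.ndarray) -> float:
    det = float(np.linalg.det(cov))
    return math.pi * math.sqrt(max(det, 0.0))


def _ellipse_polygon(mean: np.ndarray, cov: np.ndarray, scale: float = 1.0) -> Polygon:
    """Boundary {x: (x-mu)' cov^-1 (x-mu) = scale} as a shapely polygon."""
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals <= 0):
        raise ValueError("degenerate covariance: ellipse undefined")
    theta = np.linspace(0.0, 2.0 * math.pi, _ELLIPSE_VERTICES, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    pts = mean + math.sqrt(scale) * circle @ np.diag(np.sqrt(vals)) @ vecs.T
    return Polygon(pts)


def ellipse_metrics(group: NicheGroup, n_draws: int = 0, seed=None) -> NicheMetrics:
    """SEA, SEAc and convex-hull TA for a point cloud.

    SEA = pi * sqrt(det(sample covariance)); SEAc = SEA * (n-1)/(n-2).
    Collinear points give SEA = 0 with a warning.  When ``n_draws`` > 0 the
    Bayesian posterior of the area is attached too.
    """
    if group.n < 3:
        raise ValueError("need n >= 3 points")
    cov = np.cov(group.points, rowvar=False)
    sea = _sea_from_cov(cov)
    if sea == 0.0:
        warnings.warn(f"group {group.label!r}: collinear points, SEA = 0")
    seac = sea * (group.n - 1) / (group.n - 2)
    try:
        ta = float(ConvexHull(group.points).volume)  # 2-D "volume" is area
    except Exception:
        ta = 0.0
    draws = seab_posterior(group, n_draws, seed=seed) if n_draws else None
    return NicheMetrics(sea=sea, seac=seac, ta_hull=ta, seab_draws=draws)


def _niw_posterior_draws(points: np.ndarray, n_draws: int, rng: np.random.Generator):
    """Draws of (mean, covariance) under a vague normal-inverse-Wishart prior.

    Prior df = dimension + 1 with prior scale set to one sample covariance
    (scaled to the data); posterior: cov ~ IW(n + nu0, Psi0 + S),
    mean | cov ~ N(xbar, cov / n).
    """
    n, d = points.shape
    xbar = points.mean(axis=0)
    s = (points - xbar).T @ (points - xbar)
    psi0 = np.cov(points, rowvar=False)
    nu0 = d + 1
    covs = stats.invwishart.rvs(df=n + nu0, scale=psi0 + s, size=n_draws, random_state=rng)
    covs = np.asarray(covs).reshape(n_draws, d, d)
    chol = np.linalg.cholesky(covs / n)
    means = xbar + np.einsum("kij,kj->ki", chol, rng.standard_normal((n_draws, d)))
    return means, covs


def seab_posterior(group: NicheGroup, n_draws: int, seed=None) -> np.ndarray:
    """Posterior draws of the standard ellipse area (pi * sqrt(det cov))."""
    if group.n < 4:
        raise ValueError("need n >= 4 points for the posterior ellipse")
    if n_draws < 100:
        warnings.warn("n_draws < 100: posterior summaries will be noisy")
    rng = np.random.default_rng(seed)
    _, covs = _niw_posterior_draws(group.points, n_draws, rng)
    return math.pi * np.sqrt(np.maximum(np.linalg.det(covs), 0.0))


def seab_comparison_probability(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """P(SEA_b[A] < SEA_b[B]) from paired-at-random posterior draws."""
    m = min(len(draws_a), len(draws_b))
    return float(np.mean(draws_a[:m] < draws_b[:m]))


def ellipse_overlap(a: NicheGroup, b: NicheGroup) -> tuple[OverlapResult, OverlapResult]:
    """Overlap of the two SEAc ellipses, as a fraction of each group's own
    ellipse area (directional pair: a-reference, b-reference)."""
    out = []
    polys = []
    for g in (a, b):
        if g.n < 3:
            raise ValueError("need n >= 3 points per group")
        cov = np.cov(g.points, rowvar=False)
        scale = (g.n - 1) / (g.n - 2)  # area factor turning SEA into SEAc
        polys.append(_ellipse_polygon(g.points.mean(axis=0), cov, scale=scale))
    inter = polys[0].intersection(polys[1]).area
    for poly in polys:
        out.append(OverlapResult(overlap_fraction=min(1.0, inter / poly.area)))
    return out[0], out[1]


def niche_region_overlap(
    groups: list[NicheGroup],
    alpha: float = 0.95,
    n_draws: int = 500,
    n_mc: int = 400,
    seed=None,
) -> np.ndarray:
    """Posterior mean directional overlap (%) among elliptical niche regions.

    Entry (i, j) is the posterior probability that a draw from group i's
    population falls inside group j's alpha-level niche region, estimated
    by Monte Carlo over normal-inverse-Wishart posterior draws.  The matrix
    is directional (not symmetric); the diagonal self-overlap tends to
    alpha * 100.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    k = len(groups)
    q = stats.chi2.ppf(alpha, df=2)
    post = []
    for g in groups:
        if g.n < 3:
            raise ValueError("each group needs n >= 3 points")
        logger.info("niche_region_overlap: subsection/group samples may be non-independent")
        post.append(_niw_posterior_draws(g.points, n_draws, rng))

    out = np.zeros((k, k))
    z = rng.standard_normal((n_draws, n_mc, 2))
    for i in range(k):
        mu_i, cov_i = post[i]
        chol_i = np.linalg.cholesky(cov_i)
        # samples from group i's population, one cloud per posterior draw
        x = mu_i[:, None, :] + np.einsum("kab,kmb->kma", chol_i, z)
        for j in range(k):
            mu_j, cov_j = post[j]
            prec_j = np.linalg.inv(cov_j)
            dx = x - mu_j[:, None, :]
            md = np.einsum("kma,kab,kmb->km", dx, prec_j, dx)
            out[i, j] = 100.0 * float(np.mean(md <= q))
    return out
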