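"""Rank-based tests implemented from first principles.

Mann-Whitney U, Kruskal-Wallis H with Dunn's post hoc, the Skillings-Mack
statistic for incomplete blocks with a Nemenyi-style post hoc, and the
chi-square / Fisher exact tests for count tables.  scipy is used only for
reference distributions (normal, chi-square, studentized range,
hypergeometric); the statistics themselves are computed here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult", "IncompleteBlockData",
    "mann_whitney_u", "kruskal_wallis", "dunn_posthoc",
    "skillings_mack", "nemenyi_posthoc",
    "chi_square_test", "fisher_exact",
]


@dataclass
class TestResult:
    statistic: float
    statistic_name: str
    p_value: float
    df: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_sizes(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b, method: str = "normal") -> TestResult:
    """Two-sample rank test; midranks for ties, U = min(U_a, U_b).

    ``method='normal'`` (default) gives a two-sided p from the normal
    approximation with continuity correction and tie-corrected variance;
    ``method='exact'`` enumerates the permutation null (only allowed when
    both groups have <= 10 values) and ignores the continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    n = n1 + n2
    if method == "exact":
        if n1 > 10 or n2 > 10:
            raise ValueError("exact method limited to <= 10 per group")
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), n1):
            ua = float(ranks[list(comb)].sum()) - n1 * (n1 + 1) / 2.0
            if min(ua, n1 * n2 - ua) <= u + 1e-9:
                count += 1
            total += 1
        return TestResult(u, "U", min(1.0, count / total), notes="exact enumeration")

    mu = n1 * n2 / 2.0
    ties = _tie_sizes(pooled)
    tie_term = float(np.sum(ties ** 3 - ties)) / (n * (n - 1)) if ties.size else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, "U", 1.0, notes="degenerate: all values tied")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return TestResult(u, "U", p, notes="normal approximation, continuity corrected, tie-corrected variance")


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected H with chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, "H", 1.0, df=len(groups) - 1, notes="all values identical")
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = float(ranks[start:start + g.size].sum())
        h += rsum ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = _tie_sizes(pooled)
    if ties.size:
        h /= 1.0 - float(np.sum(ties ** 3 - ties)) / (n ** 3 - n)
    df = len(groups) - 1
    return TestResult(h, "H", float(stats.chi2.sf(h, df)), df=df)


def dunn_posthoc(groups, adjust: str = "none") -> np.ndarray:
    """Pairwise two-sided p matrix of Dunn's Z test on pooled midranks.

    ``adjust`` in {'none', 'bonferroni', 'holm'}; the default is no
    multiplicity adjustment.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _midranks(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    ties = _tie_sizes(pooled)
    tie_term = float(np.sum(ties ** 3 - ties)) / (12.0 * (n - 1)) if ties.size else 0.0

    raw = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        raw.append((i, j, min(1.0, 2.0 * stats.norm.sf(abs(z)))))

    pvals = np.array([p for _, _, p in raw])
    m = len(pvals)
    if adjust == "bonferroni":
        pvals = np.minimum(1.0, pvals * m)
    elif adjust == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = np.full((k, k), np.nan)
    for (i, j, _), p in zip(raw, pvals):
        out[i, j] = out[j, i] = p
    return out


# ---------------------------------------------------------------------------
# Skillings-Mack for incomplete blocks
# ---------------------------------------------------------------------------

@dataclass
class IncompleteBlockData:
    """Blocks x treatments matrix with NaN for missing cells."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >= 2 treatments")

    def usable_blocks(self) -> np.ndarray:
        """Rows with >= 2 observed cells; others cannot inform rank contrasts."""
        observed = ~np.isnan(self.matrix)
        keep = observed.sum(axis=1) >= 2
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"dropping {dropped} block(s) with < 2 observed treatments")
        return self.matrix[keep]


def _sm_components(data: IncompleteBlockData) -> tuple[np.ndarray, np.ndarray, int]:
    """Adjusted treatment rank sums A and their null covariance."""
    m = data.usable_blocks()
    k = m.shape[1]
    observed = ~np.isnan(m)
    never = np.where(observed.sum(axis=0) == 0)[0]
    if never.size:
        raise ValueError(f"treatment(s) observed in no block: {list(never + 1)}")

    a = np.zeros(k)
    for row, obs in zip(m, observed):
        ki = int(obs.sum())
        ranks = _midranks(row[obs])
        w = math.sqrt(12.0 / (ki + 1))
        centred = w * (ranks - (ki + 1) / 2.0)
        a[np.where(obs)[0]] += centred

    # null covariance: off-diagonal = -(# blocks with both j and j' observed)
    joint = observed.T.astype(float) @ observed.astype(float)
    cov = -joint
    np.fill_diagonal(cov, 0.0)
    np.fill_diagonal(cov, -cov.sum(axis=1))
    return a, cov, k


def skillings_mack(data: IncompleteBlockData) -> TestResult:
    """Rank test for treatment effects in incomplete blocks.

    Within-block midranks are weighted by sqrt(12/(k_i + 1)) and summed per
    treatment; the quadratic form against the (pseudo-inverted) null
    covariance is compared with chi-square on (treatments - 1) df.  With
    complete blocks the statistic equals Friedman's.
    """
    a, cov, k = _sm_components(data)
    sm = float(a @ np.linalg.pinv(cov) @ a)
    df = k - 1
    return TestResult(sm, "SM", float(stats.chi2.sf(sm, df)), df=df)


def nemenyi_posthoc(data: IncompleteBlockData) -> np.ndarray:
    """All-pairs post hoc p matrix from the Skillings-Mack construction.

    Each pairwise contrast A_j - A_j' is standardized by its null variance
    and referred to the studentized range distribution with infinite df,
    which on complete blocks is exactly the Friedman-Nemenyi test.
    """
    a, cov, k = _sm_components(data)
    out = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        if var <= 0:
            out[i, j] = out[j, i] = 1.0
            continue
        z = (a[i] - a[j]) / math.sqrt(var)
        q = abs(z) * math.sqrt(2.0)
        out[i, j] = out[j, i] = float(stats.studentized_range.sf(q, k, np.inf))
    return out


# ---------------------------------------------------------------------------
# Count-table tests
# ---------------------------------------------------------------------------

def chi_square_test(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square for an r x c count table (no Yates correction by
    default); errors on zero margins."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin: chi-square undefined")
    expected = np.outer(row, col) / t.sum()
    diff = np.abs(t - expected)
    if continuity and t.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff ** 2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(chi2, "chi2", float(stats.chi2.sf(chi2, df)), df=df)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table by hypergeometric
    enumeration (sum of all tables no more probable than the observed)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("Fisher exact needs a 2x2 non-negative integer table")
    t = t.astype(int)
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("zero margin: Fisher exact undefined")
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t[0, 0])
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    # odds-ratio-style statistic for reporting; p is the quantity of interest
    return TestResult(float(t[0, 0]), "Z", min(1.0, p), notes="two-sided hypergeometric enumeration")
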