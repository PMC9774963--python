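import itertools
import math

import numpy as np
import pytest
from scipy import stats

from beaktraj.nonparametric_tests import (
    IncompleteBlockData, chi_square_test, dunn_posthoc, fisher_exact,
    kruskal_wallis, mann_whitney_u, nemenyi_posthoc, skillings_mack,
)

# Printed per-individual range values used by the published sex comparisons.
F_D13C_MM = [1.87, 1.04, 1.60, 0.75, 0.76, 1.71]
M_D13C_MM = [1.60, 1.90, 1.57, 2.18, 0.72, 1.55, 1.43]
F_D13C_FL = [1.82, 0.71, 1.42, 0.06, 0.61, 1.71]
M_D13C_FL = [1.05, 1.59, 1.20, 1.02, 0.11, 1.11, 0.80]
F_D15N_FL = [4.08, 3.58, 4.30, 8.85, 1.61, 5.58]
M_D15N_FL = [4.52, 5.86, 4.29, 4.51, 1.75, 3.18, 4.27, 2.67]


class TestMannWhitney:
    def test_printed_u_values(self):
        assert mann_whitney_u(F_D13C_MM, M_D13C_MM).statistic == 17.5
        assert mann_whitney_u(F_D13C_FL, M_D13C_FL).statistic == 20.0
        assert mann_whitney_u(F_D15N_FL, M_D15N_FL).statistic == 22.0

    def test_u_sum_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            u1 = ranks[:len(a)].sum() - len(a) * (len(a) + 1) / 2
            u2 = ranks[len(a):].sum() - len(b) * (len(b) + 1) / 2
            assert u1 + u2 == pytest.approx(len(a) * len(b))
            assert mann_whitney_u(a, b).statistic == pytest.approx(min(u1, u2))

    def test_single_tied_pair(self):
        res = mann_whitney_u([1.0], [1.0])
        assert res.statistic == 0.5
        assert res.p_value == 1.0

    def test_agrees_with_scipy_statistic(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=9), rng.normal(size=11)
        ours = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.statistic == pytest.approx(min(ref.statistic, len(a) * len(b) - ref.statistic))
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_matches_enumeration_oracle(self):
        a = [1.2, 3.4, 0.4]
        b = [2.2, 5.0, 0.9, 4.4]
        res = mann_whitney_u(a, b, method="exact")
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:3].sum() - 6
        u_obs = min(u_obs, 12 - u_obs)
        hits = total = 0
        for comb in itertools.combinations(range(7), 3):
            u = ranks[list(comb)].sum() - 6
            if min(u, 12 - u) <= u_obs + 1e-9:
                hits += 1
            total += 1
        assert res.p_value == pytest.approx(hits / total)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_two_groups_consistent_with_mann_whitney(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.3, 1.0, size=12)
        p_kw = kruskal_wallis([a, b]).p_value
        p_u = mann_whitney_u(a, b).p_value
        assert abs(p_kw - p_u) < 0.05

    def test_three_identical_groups(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=8), rng.normal(size=9), rng.normal(0.5, 1, size=7)]
        ours = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_permutation_oracle(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(0.0, 1.0, 5), rng.normal(0.4, 1.0, 5), rng.normal(0.8, 1.0, 5)]
        h_obs = kruskal_wallis(groups).statistic
        pooled = np.concatenate(groups)
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h = kruskal_wallis([pooled[:5], pooled[5:10], pooled[10:]]).statistic
            if h >= h_obs:
                count += 1
        p_perm = count / n_perm
        p_asym = kruskal_wallis(groups).p_value
        assert abs(p_perm - p_asym) < 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02

    def test_dunn_matrix_shape_and_symmetry(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        m = dunn_posthoc(groups)
        assert m.shape == (4, 4)
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(m)))

    def test_dunn_adjustments_monotone(self, rng):
        groups = [rng.normal(loc, 1.0, 8) for loc in (0.0, 0.5, 1.2)]
        raw = dunn_posthoc(groups, adjust="none")
        bon = dunn_posthoc(groups, adjust="bonferroni")
        holm = dunn_posthoc(groups, adjust="holm")
        m = ~np.isnan(raw)
        assert np.all(bon[m] >= raw[m] - 1e-12)
        assert np.all(holm[m] >= raw[m] - 1e-12)
        assert np.all(bon[m] >= holm[m] - 1e-12)

    def test_dunn_oracle_two_groups(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        ranks = stats.rankdata(a + b)
        n = 6
        diff = ranks[:3].mean() - ranks[3:].mean()
        se = math.sqrt(n * (n + 1) / 12 * (2 / 3))
        expected = 2 * stats.norm.sf(abs(diff / se))
        assert dunn_posthoc([a, b])[0, 1] == pytest.approx(expected)


class TestSkillingsMack:
    def test_equals_friedman_on_complete_blocks(self, rng):
        m = rng.random((9, 5))
        ours = skillings_mack(IncompleteBlockData(m)).statistic
        ref = stats.friedmanchisquare(*m.T).statistic
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_incomplete_statistic_against_independent_construction(self):
        # independent implementation of the weighted rank-sum quadratic form
        m = np.array([
            [1.0, 2.0, 3.0],
            [2.5, np.nan, 1.5],
            [3.0, 1.0, 2.0],
            [1.0, 3.0, 2.0],
        ])
        a = np.zeros(3)
        pair_counts = np.zeros((3, 3))
        for row in m:
            obs = ~np.isnan(row)
            k = obs.sum()
            ranks = stats.rankdata(row[obs])
            a[obs] += np.sqrt(12.0 / (k + 1)) * (ranks - (k + 1) / 2.0)
            for i in np.flatnonzero(obs):
                for j in np.flatnonzero(obs):
                    if i != j:
                        pair_counts[i, j] += 1
        cov = -pair_counts
        np.fill_diagonal(cov, pair_counts.sum(axis=1))
        expected = a @ np.linalg.pinv(cov) @ a
        res = skillings_mack(IncompleteBlockData(m))
        assert res.statistic == pytest.approx(expected)
        assert res.df == 2

    def test_dominant_treatment_detected(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=(10, 3))
        m[:, 2] += 3.0  # stochastically dominant in every block
        m[rng.integers(0, 10, 3), 0] = np.nan
        res = skillings_mack(IncompleteBlockData(m))
        assert res.p_value < 0.01

    def test_unobserved_treatment_is_named(self):
        m = np.array([[1.0, 2.0, np.nan], [2.0, 1.0, np.nan], [1.5, 2.5, np.nan]])
        with pytest.raises(ValueError, match="3"):
            skillings_mack(IncompleteBlockData(m))

    def test_single_observation_blocks_dropped_with_warning(self):
        m = np.array([
            [1.0, 2.0, 3.0],
            [5.0, np.nan, np.nan],   # only one observed cell
            [2.0, 3.0, 1.0],
        ])
        with pytest.warns(UserWarning, match="dropping"):
            res = skillings_mack(IncompleteBlockData(m))
        ref = skillings_mack(IncompleteBlockData(np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0]])))
        assert res.statistic == pytest.approx(ref.statistic)


class TestNemenyi:
    def test_complete_data_matches_friedman_nemenyi_formula(self, rng):
        m = rng.random((8, 4))
        ours = nemenyi_posthoc(IncompleteBlockData(m))
        n, k = m.shape
        ranks = np.apply_along_axis(stats.rankdata, 1, m)
        mean_ranks = ranks.mean(axis=0)
        for i, j in itertools.combinations(range(k), 2):
            q = abs(mean_ranks[i] - mean_ranks[j]) / math.sqrt(k * (k + 1) / (12.0 * n))
            expected = stats.studentized_range.sf(q, k, np.inf)
            assert ours[i, j] == pytest.approx(expected, rel=1e-6)

    def test_all_equal_data_gives_p_one(self):
        m = np.ones((5, 3))
        out = nemenyi_posthoc(IncompleteBlockData(m))
        off = out[~np.isnan(out)]
        assert np.allclose(off, 1.0)

    def test_most_separated_pair_has_smallest_p(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(12, 3)) * 0.3
        m[:, 1] += 1.0
        m[:, 2] += 2.5
        out = nemenyi_posthoc(IncompleteBlockData(m))
        assert out[0, 2] == np.nanmin(out)

    def test_symmetric_with_nan_diagonal(self, rng):
        m = rng.random((6, 4))
        m[0, 1] = np.nan
        out = nemenyi_posthoc(IncompleteBlockData(m))
        assert np.allclose(out, out.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(out)))
        finite = out[~np.isnan(out)]
        assert np.all((finite >= 0) & (finite <= 1))


class TestCountTables:
    def test_chi2_independent_table(self):
        res = chi_square_test([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi2_hand_computation_2x3(self):
        table = np.array([[10, 20, 30], [20, 20, 20]])
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected_counts = row * col / table.sum()
        chi2 = ((table - expected_counts) ** 2 / expected_counts).sum()
        res = chi_square_test(table)
        assert res.statistic == pytest.approx(chi2)
        assert res.df == 2
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 2))

    def test_chi2_zero_margin_error(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])

    def test_fisher_diagonal_table_matches_enumeration(self):
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2.0 / math.comb(20, 10))

    def test_fisher_matches_scipy(self):
        for table in ([[3, 7], [5, 2]], [[8, 2], [1, 5]], [[2, 2], [2, 2]]):
            ours = fisher_exact(table)
            ref = stats.fisher_exact(table, alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
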