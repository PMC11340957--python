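"""Statistical engine vs independent oracles: rank tests, Fisher z,
categorical tests, ROC."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb as scomb

from psmbio.stats import categorical_test, compare_groups, pearson_ci, roc_auc


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_u(a, b) -> float:
    """U statistic by exhaustive pair counting (ties count half)."""
    return float(sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b))


def brute_mwu_p(a, b) -> float:
    """Two-sided p by full enumeration of group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = brute_u(a, b)
    us = np.array([
        brute_u(pooled[list(c)], np.delete(pooled, list(c)))
        for c in combinations(range(len(pooled)), n1)
    ])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def brute_fisher_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (sum of tables with
    probability <= observed)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (scomb(col1, x, exact=True) * scomb(n - col1, row1 - x, exact=True)
                / scomb(n, row1, exact=True))

    p_obs = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def brute_auc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# compare_groups
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_identical_groups_rank_test(self):
        res = compare_groups(np.arange(1, 21), np.arange(1, 21), test="mann_whitney")
        assert res.statistic == 200.0  # U = n^2 / 2
        assert res.p == pytest.approx(1.0)

    def test_separated_distributions(self, rng):
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000) + 1.0
        res = compare_groups(a, b)
        assert res.p < 1e-10

    def test_selection_uses_shapiro(self, rng):
        normal_a = rng.standard_normal(80)
        normal_b = rng.standard_normal(80) + 0.2
        skewed = rng.lognormal(0, 1.5, 80)
        assert compare_groups(normal_a, normal_b).test_used == "welch_t"
        assert compare_groups(normal_a, skewed).test_used == "mann_whitney"

    def test_u_statistic_matches_pair_counting(self, rng):
        a = [1, 2, 3, 4, 5]
        b = [2, 3, 4, 5, 6]
        res = compare_groups(a, b, test="mann_whitney")
        assert res.statistic == brute_u(a, b) == 8.0
        for _ in range(20):
            x = rng.integers(0, 6, rng.integers(3, 9)).astype(float)
            y = rng.integers(0, 6, rng.integers(3, 9)).astype(float)
            if np.ptp(np.r_[x, y]) == 0:
                continue
            res = compare_groups(x, y, test="mann_whitney")
            assert res.statistic == brute_u(x, y)

    def test_small_sample_p_matches_enumeration(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(3, 8, 2)
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = compare_groups(x, y, test="mann_whitney")
            assert res.p == pytest.approx(brute_mwu_p(x, y), abs=1e-9)

    def test_welch_matches_pooled_for_equal_variance_equal_n(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + a.mean() + 0.1
        welch = compare_groups(a, b, test="welch_t")
        pooled = sps.ttest_ind(a, b, equal_var=True)
        assert welch.p == pytest.approx(pooled.pvalue, rel=1e-6)

    def test_constant_group_falls_back_to_rank_test_with_warning(self):
        res = compare_groups([5.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.test_used == "mann_whitney"
        assert any("constant" in w for w in res.warnings)

    def test_missing_values_dropped_and_counted(self):
        res = compare_groups([1, 2, 3, np.nan], [4, 5, 6, np.nan, np.nan])
        assert res.n_a == 3 and res.n_b == 3 and res.n_dropped == 3

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [1, 2, 3])

    def test_sensitivity_reports_other_test(self, rng):
        res = compare_groups(rng.standard_normal(50), rng.standard_normal(50))
        assert res.p_other is not None
        assert res.decision_flips in (True, False)


# ---------------------------------------------------------------------------
# pearson_ci
# ---------------------------------------------------------------------------

def vectors_with_exact_r(r: float, n: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    y = y - y.mean()
    y -= x * (x @ y) / (x @ x)
    y /= y.std()
    return x, r * x + np.sqrt(1 - r * r) * y


class TestPearsonCi:
    def test_published_interval_case(self):
        """r = 0.36 at n = 224: Fisher z gives (0.24, 0.47) at 2 dp."""
        x, y = vectors_with_exact_r(0.36, 224)
        res = pearson_ci(x, y)
        assert res.r == pytest.approx(0.36, abs=1e-12)
        assert round(res.ci_low, 2) == 0.24
        assert round(res.ci_high, 2) == 0.47

    def test_perfect_correlation_clamped_with_warning(self):
        x = np.arange(10.0)
        res = pearson_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.warnings
        assert res.ci_high <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))

    def test_complete_case_n(self):
        x = np.r_[np.arange(20.0), np.nan]
        y = np.r_[np.arange(20.0) + np.random.default_rng(0).normal(0, 1, 20), 3.0]
        assert pearson_ci(x, y).n == 20

    def test_p_matches_scipy(self, rng):
        x = rng.standard_normal(100)
        y = 0.3 * x + rng.standard_normal(100)
        res = pearson_ci(x, y)
        assert res.p == pytest.approx(sps.pearsonr(x, y).pvalue, rel=1e-6)

    def test_null_coverage_quick(self):
        """~95% of null CIs cover zero (300 reps; the full 2000-rep check
        runs in the acceptance suite)."""
        rng = np.random.default_rng(11)
        covered = 0
        for _ in range(150):
            res = pearson_ci(rng.standard_normal(224), rng.standard_normal(224))
            covered += res.ci_low <= 0 <= res.ci_high
        assert 0.90 <= covered / 150 <= 1.0


# ---------------------------------------------------------------------------
# categorical_test
# ---------------------------------------------------------------------------

class TestCategorical:
    def test_balanced_table_null(self):
        res = categorical_test([[10, 10], [10, 10]])
        assert res["test_used"] == "chi_squared"
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_diagonal_table_fisher(self):
        res = categorical_test([[5, 0], [0, 5]])
        assert res["test_used"] == "fisher_exact"
        assert res["p"] == pytest.approx(2 / 252)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            table = rng.integers(0, 5, (2, 2))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            res = categorical_test(table)
            if res["test_used"] == "fisher_exact":
                assert res["p"] == pytest.approx(brute_fisher_p(table), abs=1e-9)

    def test_2xk_collapse_rule(self):
        res = categorical_test([[50, 40, 2, 1], [45, 50, 1, 2]])
        assert res["columns_collapsed"] >= 1
        assert 0 <= res["p"] <= 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [1, 2]])

    def test_null_calibration_uniform_p(self, rng):
        """Independent binaries at cohort-like prevalences give ~uniform p."""
        ps = []
        for _ in range(300):
            a = rng.random(224) < 0.21
            b = rng.random(224) < 0.37
            table = [[int((a & b).sum()), int((a & ~b).sum())],
                     [int((~a & b).sum()), int((~a & ~b).sum())]]
            ps.append(categorical_test(table)["p"])
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.10


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res["auc"] == 1.0

    def test_independent_scores_near_half(self, rng):
        res = roc_auc(rng.standard_normal(4000), rng.random(4000) < 0.3)
        assert res["auc"] == pytest.approx(0.5, abs=0.03)

    def test_low_orientation_brute_force_case(self):
        res = roc_auc([0.1, 0.2, 0.3, 0.4], [1, 1, 0, 0], positive_direction="low")
        assert res["auc"] == 1.0
        assert res["auc"] == brute_auc([-0.1, -0.2, -0.3, -0.4], [1, 1, 0, 0])

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 16))
            scores = rng.integers(0, 5, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_auc(scores, labels)
            assert res["auc"] == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    def test_auc_equals_u_over_n1n2(self, rng):
        """Identity with the Mann-Whitney U from compare_groups."""
        pos = rng.standard_normal(40) + 0.5
        neg = rng.standard_normal(60)
        res = roc_auc(np.r_[pos, neg], np.r_[np.ones(40), np.zeros(60)].astype(bool))
        u = compare_groups(pos, neg, test="mann_whitney").statistic
        assert res["auc"] == pytest.approx(u / (40 * 60), abs=1e-12)

    def test_roc_points_against_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        scores = rng.standard_normal(300)
        labels = (scores + rng.standard_normal(300)) > 0
        res = roc_auc(scores, labels)
        assert res["auc"] == pytest.approx(
            sklearn.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])
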