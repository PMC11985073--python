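import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ethofeed as ef


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def fisher_p_enumeration(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r, s = a + b, a + c  # row-1 and col-1 margins

    def log_p(k):
        return (
            math.lgamma(r + 1) - math.lgamma(k + 1) - math.lgamma(r - k + 1)
            + math.lgamma(n - r + 1) - math.lgamma(s - k + 1) - math.lgamma(n - r - s + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(s + 1) - math.lgamma(n - s + 1))
        )

    lo, hi = max(0, r + s - n), min(r, s)
    probs = {k: math.exp(log_p(k)) for k in range(lo, hi + 1)}
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-10)))


def mann_whitney_p_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )
    u_obs = u_stat(tuple(range(nx)))
    us = [u_stat(idx) for idx in itertools.combinations(range(len(pooled)), nx)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[5, 0], [0, 5]], 2 / 252),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert ef.fisher_exact_2x2(table).p == pytest.approx(expected, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert ef.fisher_exact_2x2([[7, 3], [7, 3]]).p == pytest.approx(1.0)

    def test_non_2x2_redirects(self):
        with pytest.raises(ValueError, match="chi_square"):
            ef.fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=15), min_size=4, max_size=4))
    def test_matches_enumeration_oracle(self, cells):
        table = [cells[:2], cells[2:]]
        if sum(cells) == 0:
            return
        assert ef.fisher_exact_2x2(table).p == pytest.approx(
            fisher_p_enumeration(table), rel=1e-8, abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
    def test_invariant_under_row_col_swap_and_transpose(self, cells):
        (a, b), (c, d) = table = [cells[:2], cells[2:]]
        if sum(cells) == 0:
            return
        p = ef.fisher_exact_2x2(table).p
        for variant in ([[c, d], [a, b]], [[b, a], [d, c]], [[a, c], [b, d]]):
            assert ef.fisher_exact_2x2(variant).p == pytest.approx(p, rel=1e-10)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


class TestChiSquare:
    def test_perfect_fit(self):
        result = ef.chi_square_test([[10, 10], [10, 10]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_hand_computation(self):
        result = ef.chi_square_test([[10, 20], [20, 10]])
        assert result.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert result.df == 1

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            ef.chi_square_test([[0, 5], [0, 7]])

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="below 5"):
            ef.chi_square_test([[1, 9], [2, 8]])

    def test_qualitative_agreement_with_fisher_at_large_n(self):
        strong = [[80, 20], [20, 80]]
        weak = [[52, 48], [48, 52]]
        assert ef.chi_square_test(strong).p < 0.01 and ef.fisher_exact_2x2(strong).p < 0.01
        assert ef.chi_square_test(weak).p > 0.1 and ef.fisher_exact_2x2(weak).p > 0.1

    def test_rxc_degrees_of_freedom(self):
        result = ef.chi_square_test([[10, 12, 14], [14, 12, 10]])
        assert result.df == 2


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_enumeration_example(self):
        result = ef.mann_whitney([1, 2], [3, 4])
        assert result.statistic == 0.0
        assert result.p == pytest.approx(2 / 6, rel=1e-12)
        assert result.extra["method"] == "exact"

    def test_identical_samples_symmetry(self):
        result = ef.mann_whitney([1, 2, 3], [1, 2, 3])
        assert result.p == pytest.approx(1.0)

    def test_censored_flag_rejected(self):
        with pytest.raises(ValueError, match="uncensored"):
            ef.mann_whitney([1, 2], [3, 4], censored=True)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 50, allow_nan=False), min_size=2, max_size=6),
        st.lists(st.floats(0.1, 50, allow_nan=False), min_size=2, max_size=6),
    )
    def test_matches_permutation_enumeration(self, x, y):
        if np.unique(np.concatenate([x, y])).size < len(x) + len(y):
            return  # exact path requires no ties
        result = ef.mann_whitney(x, y)
        assert result.extra["method"] == "exact"
        assert result.p == pytest.approx(mann_whitney_p_enumeration(x, y), rel=1e-9)

    def test_switches_to_asymptotic_for_large_or_tied_samples(self):
        rng = np.random.default_rng(0)
        big = ef.mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert big.extra["method"] == "asymptotic"
        tied = ef.mann_whitney([1, 1, 2], [2, 3, 3])
        assert tied.extra["method"] == "asymptotic"

    def test_shifted_lognormal_power(self):
        # shift = 5x scale at n = 80/arm: rejects at 1e-4 in >= 80% of reps
        rng = np.random.default_rng(123)
        reps, rejections = 200, 0
        for _ in range(reps):
            a = rng.lognormal(np.log(2.0), 0.5, 80)
            b = rng.lognormal(np.log(10.0), 0.5, 80)
            rejections += ef.mann_whitney(a, b).p < 1e-4
        assert rejections / reps >= 0.80


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


class TestKruskalDunn:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        result = ef.kruskal_wallis_dunn([g, g, g])
        assert result.H == pytest.approx(0.0, abs=1e-12)
        assert result.p_overall == pytest.approx(1.0)
        assert all(c.p_adjusted == 1.0 for c in result.pairwise)

    def test_hand_rank_oracle(self):
        # groups {1,2},{3,4},{5,6}: mean ranks 1.5, 3.5, 5.5, no ties
        # H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2) = 32/7
        result = ef.kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6]])
        assert result.H == pytest.approx(32 / 7, rel=1e-12)
        assert result.df == 2

    def test_dunn_pair_count_and_adjustment(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]]
        all_pairs = ef.kruskal_wallis_dunn(groups, pairs="all")
        vs_first = ef.kruskal_wallis_dunn(groups, pairs="vs-first")
        assert len(all_pairs.pairwise) == 6
        assert len(vs_first.pairwise) == 3
        for c in vs_first.pairwise:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))
            assert c.pair[0] == 0

    def test_dunn_z_matches_hand_formula_no_ties(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        result = ef.kruskal_wallis_dunn(groups)
        n = 6
        se = np.sqrt(n * (n + 1) / 12 * (1 / 2 + 1 / 2))
        assert result.pairwise[0].z == pytest.approx((1.5 - 3.5) / se)

    def test_errors(self):
        with pytest.raises(ValueError, match="3 groups"):
            ef.kruskal_wallis_dunn([[1], [2]])
        with pytest.raises(ValueError, match="non-empty"):
            ef.kruskal_wallis_dunn([[1, 2], [], [3, 4]])

    def test_time_course_pairwise_separation(self):
        # strongly separated control vs first arm reaches adjusted significance
        rng = np.random.default_rng(5)
        control = rng.lognormal(np.log(2), 0.5, 60)
        slowed = [rng.lognormal(np.log(10), 0.5, 45) for _ in range(4)]
        result = ef.kruskal_wallis_dunn([control, *slowed], pairs="vs-first")
        assert result.pairwise[0].p_adjusted < 0.05


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps, m, expected",
        [
            ([0.01], 3, [0.03]),
            ([0.5], 3, [1.0]),
            ([0.2], 1, [0.2]),
        ],
    )
    def test_definition(self, ps, m, expected):
        assert ef.bonferroni(ps, m) == pytest.approx(expected)

    def test_family_size_errors(self):
        with pytest.raises(ValueError):
            ef.bonferroni([0.1], 0)
        with pytest.raises(ValueError, match="smaller"):
            ef.bonferroni([0.1, 0.2, 0.3], 2)


def test_all_p_values_in_unit_interval_and_relabel_invariant():
    rng = np.random.default_rng(17)
    a, b = rng.normal(size=12), rng.normal(1.0, 1.0, 15)
    table = [[8, 4], [3, 9]]
    for p in (
        ef.fisher_exact_2x2(table).p,
        ef.chi_square_test(table).p,
        ef.mann_whitney(a, b).p,
        ef.kruskal_wallis_dunn([a, b, rng.normal(size=10)]).p_overall,
    ):
        assert 0.0 <= p <= 1.0
    assert ef.mann_whitney(b, a).p == pytest.approx(ef.mann_whitney(a, b).p)
    assert ef.fisher_exact_2x2([[3, 9], [8, 4]]).p == pytest.approx(
        ef.fisher_exact_2x2(table).p
    )
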