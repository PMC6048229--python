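"""Unit and property tests for the shared discrete-data primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gwcausal import (
    ContingencyTable,
    DiscreteSample,
    DomainSpec,
    MultiSample,
    PMF,
    chi_square_test,
    estimate_conditional,
    expected_counts,
    fisher_exact,
    joint_counts,
    permutation_pvalue,
    renyi_entropy0,
    shannon_entropy,
    tabulate,
)
from gwcausal.discrete_core import (
    batch_chi2_stats,
    randomized_tail_pvalue,
    sample_null_tables,
)

from conftest import make_sample


# ---------------------------------------------------------------------------
# domains, samples, pmfs
# ---------------------------------------------------------------------------

class TestDomainsAndSamples:
    def test_cyclic_subtraction_wraps_modulo_m(self):
        d = DomainSpec("cyclic", 3)
        assert list(d.subtract([0, 1, 2], [2, 2, 2])) == [1, 2, 0]

    def test_integer_subtraction_is_ordinary(self):
        d = DomainSpec("integer", 3)
        assert list(d.subtract([0, 1, 2], [2, 2, 2])) == [-2, -1, 0]

    @pytest.mark.parametrize("x,y", [([], []), ([0], [0, 1]), ([3], [0])])
    def test_invalid_samples_rejected(self, x, y):
        with pytest.raises(ValueError):
            make_sample(x, y)

    def test_swapped_exchanges_roles(self):
        s = make_sample([0, 1, 2], [1, 0, 1])
        sw = s.swapped()
        assert list(sw.x) == [1, 0, 1] and sw.x_domain.m == 2

    @pytest.mark.parametrize("probs", [[0.5, 0.6], [-0.1, 1.1], []])
    def test_pmf_validation(self, probs):
        with pytest.raises(ValueError):
            PMF(np.array(probs))


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

class TestTabulate:
    def test_direct_counts(self):
        t = tabulate(make_sample([0, 0, 1, 2], [0, 1, 0, 1]))
        assert t.counts.tolist() == [[1, 1, 0], [1, 0, 1]]
        assert (t.n0, t.n1, t.n) == (2, 2, 4)

    def test_two_snps_enumerate_nine_cells(self):
        ms = MultiSample(np.array([[0, 0], [1, 2], [2, 1]]),
                         np.array([0, 1, 0]))
        t = tabulate(ms)
        assert t.C == 9 and t.q == 2
        assert chi_square_test(t).df == 8

    def test_degenerate_margin(self):
        t = tabulate(make_sample([1, 1, 1, 1], [0, 0, 0, 0]))
        assert t.n1 == 0 and (t.counts > 0).sum() == 1

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            tabulate(make_sample([0, 1], [0, 2], ym=3))

    def test_out_of_range_genotype_names_row(self):
        ms = MultiSample(np.array([[0], [3]]), np.array([0, 1]))
        with pytest.raises(ValueError, match="row 1"):
            tabulate(ms)

    def test_tsv_round_trip(self, tmp_path):
        t = tabulate(make_sample([0, 0, 1, 2], [0, 1, 0, 1]))
        p = tmp_path / "table.tsv"
        t.to_tsv(p)
        back = ContingencyTable.from_tsv(p)
        assert np.array_equal(back.counts, t.counts)


class TestExpectedCounts:
    def test_symmetric_margins(self):
        t = ContingencyTable(np.array([[30, 10], [10, 30]]), [0, 1])
        assert np.allclose(expected_counts(t), 20.0)

    def test_hand_arithmetic(self):
        t = ContingencyTable(np.array([[1, 1, 0], [1, 0, 1]]), [0, 1, 2])
        assert np.allclose(expected_counts(t)[0], [1.0, 0.5, 0.5])

    def test_zero_response_row(self):
        t = ContingencyTable(np.array([[3, 4], [0, 0]]), [0, 1])
        assert np.allclose(expected_counts(t)[1], 0.0)

    def test_empty_table_errors(self):
        t = ContingencyTable(np.zeros((2, 2), dtype=int), [0, 1])
        with pytest.raises(ValueError):
            expected_counts(t)


# ---------------------------------------------------------------------------
# chi-square and Fisher tests
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        t = ContingencyTable(np.array([[10, 20, 30], [10, 20, 30]]),
                             [0, 1, 2])
        r = chi_square_test(t)
        assert r.statistic == pytest.approx(0.0) and r.p_value == 1.0

    def test_hand_computed_statistic(self):
        t = ContingencyTable(np.array([[30, 10], [10, 30]]), [0, 1])
        assert chi_square_test(t).statistic == pytest.approx(20.0)

    def test_df_is_three_to_q_minus_one(self):
        t = tabulate(make_sample([0, 1, 2, 0], [0, 1, 0, 1]))
        assert chi_square_test(t).df == 2

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            c = rng.integers(2, 6)
            counts = rng.integers(1, 40, size=(2, c))
            t = ContingencyTable(counts, list(range(c)), q=1)
            ours = chi_square_test(t, df_convention="classical")
            ref_stat, ref_p, ref_df, _ = stats.chi2_contingency(
                counts, correction=False)
            assert ours.statistic == pytest.approx(ref_stat, abs=1e-10)
            assert ours.df == ref_df
            assert ours.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_empty_response_margin_directs_to_fisher(self):
        t = ContingencyTable(np.array([[3, 4], [0, 0]]), [0, 1])
        with pytest.raises(ValueError, match="fisher"):
            chi_square_test(t)

    def test_zero_total_columns_dropped_df_kept(self):
        full = ContingencyTable(np.array([[5, 7], [6, 2]]), [0, 1])
        padded = ContingencyTable(np.array([[5, 0, 7], [6, 0, 2]]),
                                  [0, 1, 2])
        assert chi_square_test(padded).statistic == pytest.approx(
            chi_square_test(full).statistic)
        assert chi_square_test(padded).df == 2


def _fisher_enumeration_p(counts):
    """Exact conditional p for a 2x2 table by enumerating the support."""
    a, b = counts[0]
    c, d = counts[1]
    r0, c0, n = a + b, a + c, a + b + c + d
    obs = (math.comb(c0, a) * math.comb(n - c0, r0 - a))
    total = math.comb(n, r0)
    p = 0
    for aa in range(max(0, r0 + c0 - n), min(r0, c0) + 1):
        w = math.comb(c0, aa) * math.comb(n - c0, r0 - aa)
        if w <= obs:
            p += w
    return p / total


class TestFisher:
    def test_diagonal_example(self):
        t = ContingencyTable(np.array([[5, 0], [0, 5]]), [0, 1])
        assert fisher_exact(t).p_value == pytest.approx(2 / math.comb(10, 5))

    def test_proportional_rows_maximal_p(self):
        t = ContingencyTable(np.array([[10, 20], [10, 20]]), [0, 1])
        assert fisher_exact(t).p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 12, size=(2, 2))
            if counts.sum(axis=0).min() == 0 or counts.sum() == 0 \
                    or counts.sum(axis=1).min() == 0:
                continue
            t = ContingencyTable(counts, [0, 1])
            assert fisher_exact(t).p_value == pytest.approx(
                _fisher_enumeration_p(counts), abs=1e-9)

    def test_monte_carlo_for_wide_tables_is_seeded(self):
        t = ContingencyTable(np.array([[8, 1, 0], [1, 0, 7]]), [0, 1, 2])
        p1 = fisher_exact(t, seed=3).p_value
        p2 = fisher_exact(t, seed=3).p_value
        assert p1 == p2 and p1 < 0.05


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

class TestEntropies:
    @pytest.mark.parametrize("p,expected", [
        ([1.0], 0.0),
        ([0.5, 0.5], 1.0),
        ([0.6, 0.3, 0.1], 1.2954618442383218),
    ])
    def test_shannon_known_values(self, p, expected):
        assert shannon_entropy(np.array(p)) == pytest.approx(expected)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_shannon_permutation_invariant_and_bounded(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = shannon_entropy(p)
        assert shannon_entropy(p[::-1]) == pytest.approx(h)
        assert -1e-12 <= h <= np.log2(len(p)) + 1e-12

    def test_uniform_maximizes_shannon(self, rng):
        k = 5
        uni = shannon_entropy(np.full(k, 1 / k))
        for _ in range(50):
            p = rng.dirichlet(np.ones(k))
            assert shannon_entropy(p) <= uni + 1e-12

    @pytest.mark.parametrize("p,expected", [
        ([0.5, 0.5], 1.0),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.6, 0.3, 0.1], np.log2(3)),
    ])
    def test_renyi_zero_counts_support(self, p, expected):
        assert renyi_entropy0(np.array(p)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# conditional estimation
# ---------------------------------------------------------------------------

class TestEstimateConditional:
    def test_direct_counts(self):
        cond = estimate_conditional(make_sample([0, 0, 1], [0, 1, 1],
                                                xm=2, ym=2))
        assert np.allclose(cond.marginal, [2 / 3, 1 / 3])
        assert np.allclose(cond.rows, [[0.5, 0.5], [0, 1]])

    def test_constant_x_single_group(self):
        cond = estimate_conditional(make_sample([0, 0, 0], [0, 1, 1],
                                                xm=1, ym=2))
        assert np.allclose(cond.marginal, [1.0])

    def test_matches_brute_force_counting(self, rng):
        x = rng.integers(0, 4, 300)
        y = rng.integers(0, 3, 300)
        cond = estimate_conditional(make_sample(x, y, xm=4, ym=3))
        for i in range(4):
            for j in range(3):
                expected = np.sum((x == i) & (y == j)) / max(np.sum(x == i), 1)
                if np.sum(x == i):
                    assert cond.rows[i, j] == pytest.approx(expected)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 100)
            y = rng.integers(0, 4, 100)
            cond = estimate_conditional(make_sample(x, y, xm=5, ym=4))
            sums = cond.rows[~cond.undefined].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

class TestPermutationEngine:
    def test_constant_statistic_gives_p_one(self):
        s = make_sample([0, 1, 2, 0], [0, 1, 0, 1])
        r = permutation_pvalue(lambda sm: 1.0, s, B=99, seed=0)
        assert r.p_value == 1.0

    def test_invalid_B(self):
        s = make_sample([0, 1], [0, 1])
        with pytest.raises(ValueError):
            permutation_pvalue(lambda sm: 0.0, s, B=0, seed=0)

    def test_reproducible_for_fixed_seed(self):
        s = make_sample([0, 1, 2, 0, 1, 2] * 5, [0, 1, 0, 1, 1, 0] * 5)

        def stat(sm):
            return abs(np.corrcoef(sm.x, sm.y)[0, 1])

        assert (permutation_pvalue(stat, s, B=199, seed=5).p_value
                == permutation_pvalue(stat, s, B=199, seed=5).p_value)

    def test_null_pvalues_uniform(self):
        """Empirical CDF of p under x independent of y is close to uniform."""
        rng = np.random.default_rng(0)

        def stat(sm):
            return abs(np.corrcoef(sm.x, sm.y)[0, 1])

        ps = []
        for rep in range(500):
            s = make_sample(rng.integers(0, 3, 60), rng.integers(0, 2, 60))
            ps.append(permutation_pvalue(stat, s, B=999, seed=rep).p_value)
        assert stats.kstest(ps, "uniform").statistic <= 0.05

    def test_null_tables_preserve_margins(self, rng):
        counts = np.array([[40, 12], [25, 30], [9, 4]])
        tables = sample_null_tables(counts, 200, rng)
        assert np.all(tables.sum(axis=2) == counts.sum(axis=1))
        assert np.all(tables.sum(axis=1) == counts.sum(axis=0))

    def test_null_tables_match_literal_permutation_law(self, rng):
        """Hypergeometric table sampling equals shuffling y and re-counting."""
        x = np.repeat([0, 1, 2], [30, 20, 10])
        y = np.array([1] * 24 + [0] * 36)
        counts = joint_counts(make_sample(x, y))
        direct = sample_null_tables(counts, 4000, rng)[:, :, 1]
        shuffled = np.array([
            [np.sum(yy[x == g]) for g in range(3)]
            for yy in (rng.permutation(y) for _ in range(4000))])
        # compare the first-group count distributions
        for g in range(3):
            d = stats.ks_2samp(direct[:, g], shuffled[:, g]).statistic
            assert d < 0.05

    def test_wide_response_null_tables(self, rng):
        counts = np.array([[10, 5, 3], [2, 8, 12]])
        tables = sample_null_tables(counts, 50, rng)
        assert np.all(tables.sum(axis=2) == counts.sum(axis=1))
        assert np.all(tables.sum(axis=1) == counts.sum(axis=0))

    def test_randomized_rank_uniform_on_degenerate_statistic(self):
        """Tie-splitting keeps p uniform even when all statistics are equal."""
        rng = np.random.default_rng(3)
        ps = [randomized_tail_pvalue(0.0, np.zeros(99), rng)
              for _ in range(2000)]
        assert stats.kstest(ps, "uniform").statistic < 0.05

    def test_batch_chi2_matches_scipy(self, rng):
        tables = rng.integers(1, 30, size=(50, 3, 2)).astype(float)
        ours = batch_chi2_stats(tables)
        for t, s in zip(tables, ours):
            ref = stats.chi2_contingency(t, correction=False)[0]
            assert s == pytest.approx(ref, abs=1e-10)
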