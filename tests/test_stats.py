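"""Exact nonparametric statistics: enumeration correctness and invariants."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from emphyquant.stats import (fold_change, kruskal_wallis,
                              mann_whitney_exact, spearman, summarize,
                              wilcoxon_signed_rank_exact)
from conftest import mann_whitney_oracle_p


class TestMannWhitney:
    @pytest.mark.parametrize("x, y, p", [
        # complete separation at the cohort sizes of a small mouse study
        ([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], 2 / 252),
        ([1, 2, 3, 4], [5, 6, 7, 8], 2 / 70),
        ([1, 2, 3, 4, 5], [6, 7, 8, 9], 2 / 126),
        # one inverted cross-group pair (U = 1) at 5 v 4
        ([1, 2, 3, 4, 6], [5, 7, 8, 9], 4 / 126),
    ])
    def test_exact_p_small_cohorts(self, x, y, p):
        res = mann_whitney_exact(x, y)
        assert res.exact
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_u_statistic_one_inversion(self):
        assert mann_whitney_exact([1, 2, 3, 4, 6], [5, 7, 8, 9]).statistic == 1

    @pytest.mark.parametrize("n1, n2", list(product(range(1, 11), repeat=2)))
    def test_minimal_p_law_complete_separation(self, n1, n2):
        """Complete separation gives p = 2/C(n1+n2, n1) for all small sizes."""
        x = list(range(n1))
        y = list(range(n1, n1 + n2))
        p = mann_whitney_exact(x, y).p_two_sided
        expected = min(1.0, 2.0 / math.comb(n1 + n2, n1))
        assert p == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_enumeration_oracle(self, seed):
        """Exact p equals counting over every label assignment, with ties."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)
        y = rng.integers(0, 6, size=n2).astype(float)
        res = mann_whitney_exact(x, y)
        assert res.p_two_sided == pytest.approx(mann_whitney_oracle_p(x, y))

    def test_symmetry(self):
        x, y = [3.1, 4.5, 2.2, 8.0], [5.5, 1.0, 9.9]
        assert mann_whitney_exact(x, y).p_two_sided == pytest.approx(
            mann_whitney_exact(y, x).p_two_sided)

    def test_degenerate_identical_values(self):
        res = mann_whitney_exact([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.p_two_sided == 1.0

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.8, 1, 15)
        res = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert not res.exact
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=6),
           st.lists(st.integers(0, 20), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_p_in_unit_interval_and_symmetric(self, x, y):
        rx = mann_whitney_exact(x, y)
        ry = mann_whitney_exact(y, x)
        assert 0 < rx.p_two_sided <= 1
        assert rx.p_two_sided == pytest.approx(ry.p_two_sided)


class TestWilcoxon:
    def test_all_positive_five(self):
        """Five concordant pairs: p = 2/32, the smallest attainable."""
        res = wilcoxon_signed_rank_exact([0.3, 1.2, 0.7, 2.0, 0.1])
        assert res.exact and res.p_two_sided == pytest.approx(2 / 32)

    def test_balanced_pair_is_uninformative(self):
        res = wilcoxon_signed_rank_exact([1.0, -1.0])
        assert res.p_two_sided == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank_exact([0.0, 0.0])
        assert res.degenerate and res.p_two_sided == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sign_flip_oracle(self, seed):
        """Exact p equals brute-force enumeration of all 2^n sign patterns."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.integers(-5, 6, size=n).astype(float)
        d = d[d != 0]
        if d.size == 0:
            d = np.array([1.0])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in product([True, False], repeat=d.size)]
        lo = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
        hi = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
        expected = min(1.0, 2 * min(lo, hi))
        assert wilcoxon_signed_rank_exact(d).p_two_sided == pytest.approx(
            expected)

    def test_large_sample_matches_scipy_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, 30)
        res = wilcoxon_signed_rank_exact(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert not res.exact
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestKruskalWallis:
    def test_no_separation(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.p_two_sided == 1.0

    def test_h_formula_fully_separated_ranks(self):
        """Groups holding ranks (1,2), (3,4), (5,6) give H = 32/7."""
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_label_permutation_invariance(self):
        groups = [[1.0, 5.0, 2.0], [4.0, 3.0], [6.0, 0.5]]
        h1 = kruskal_wallis(groups, exact=False).statistic
        h2 = kruskal_wallis([groups[2], groups[0], groups[1]],
                            exact=False).statistic
        assert h1 == pytest.approx(h2)

    def test_matches_scipy_chi_square_branch(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.5, 1.0)]
        res = kruskal_wallis(groups, exact=False)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_exact_enumeration_upper_bounds_minimal_p(self):
        """Most extreme 2+2 split: exact p is 2/C(4,2) by symmetry."""
        res = kruskal_wallis([[1, 2], [9, 10]])
        assert res.exact
        assert res.p_two_sided == pytest.approx(2 / 6)

    def test_single_group_invalid(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestSpearman:
    def test_perfect_negative_monotone(self):
        res = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_tied_midranks_align(self):
        res = spearman([1, 2, 2, 4], [10, 20, 20, 40])
        assert res.rho == pytest.approx(1.0)

    def test_exact_permutation_p_at_n4(self):
        """rho = 1 at n = 4: only 2 of the 24 permutations reach |rho| = 1."""
        res = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.exact
        assert res.p_two_sided == pytest.approx(2 / 24)

    def test_sign_flip_antisymmetry(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [3.0, 1.0, 7.0, 2.0, 9.0]
        r1 = spearman(x, y)
        r2 = spearman(x, [-v for v in y])
        assert r1.rho == pytest.approx(-r2.rho)

    def test_zero_variance_flagged(self):
        res = spearman([1, 2, 3], [5, 5, 5])
        assert res.undefined

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=15)
        y = 0.6 * x + rng.normal(size=15)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert not res.exact
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestSummaries:
    def test_median_and_range(self):
        s = summarize([3.0, 1.0, 4.0, 2.0])
        assert (s.median, s.min, s.max, s.n) == (2.5, 1.0, 4.0, 4)

    @pytest.mark.parametrize("a, b, digits, printed", [
        (10.98, 1.1, 2, 9.98),
        (5.147, 1.1, 1, 4.7),
        (10.98, 5.147, 2, 2.13),
    ])
    def test_fold_change_printed_precision(self, a, b, digits, printed):
        assert round(fold_change(a, b), digits) == printed

    def test_zero_reference_invalid(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
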