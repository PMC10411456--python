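"""Exact tests against independent enumeration oracles and scipy."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from milkswap.stats import (
    bonferroni_adjust,
    chi_square,
    fisher_exact_2x2,
    wilcoxon_signed_rank,
)


def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def wilcoxon_oracle(x, y):
    """Two-sided p by enumerating every sign assignment explicitly."""
    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((0, 1), repeat=m)
    ]
    total = 2**m
    p_le = sum(v <= w for v in sums) / total
    p_ge = sum(v >= w for v in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestFisherExact:
    def test_perfect_separation_5v5(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]).p_value == pytest.approx(
            2 / 252, abs=1e-15
        )

    def test_identical_rows_show_no_association(self):
        assert fisher_exact_2x2([[7, 3], [7, 3]]).p_value == 1.0

    def test_rejects_non_integer_cells(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_exact_2x2([[a, b], [c, d]]).p_value == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_scipy_cross_check(self, cells):
        a, b, c, d = cells
        ours = fisher_exact_2x2([[a, b], [c, d]]).p_value
        ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, abs=1e-9)


class TestChiSquare:
    def test_independence_gives_zero_statistic(self):
        res = chi_square([[50, 50], [50, 50]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_perfect_association_hand_computation(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.method.endswith("df1")

    def test_degrees_of_freedom_for_rectangular_table(self, rng):
        counts = rng.integers(1, 40, size=(4, 7))
        assert chi_square(counts).method.endswith("df18")

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 5]])


class TestWilcoxonSignedRank:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_six_concordant_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [v + i + 1 for i, v in enumerate(x)]  # distinct positive shifts
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(2 / 64, abs=1e-15)

    @settings(max_examples=60, derandomize=True)
    @given(n=st.integers(1, 12), seed=st.integers(0, 2**16))
    def test_matches_enumeration_oracle_with_ties(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=n).astype(float)  # many ties and zeros
        y = rng.integers(0, 4, size=n).astype(float)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_oracle(x, y), abs=1e-12
        )

    def test_exact_path_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(0.5, 1.0, size=15)
        ref = sps.wilcoxon(x, y, mode="exact").pvalue
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(ref, abs=1e-12)

    def test_normal_path_matches_scipy_approximation(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(0.3, 1.0, size=80)
        ref = sps.wilcoxon(x, y, mode="approx", correction=False).pvalue
        ours = wilcoxon_signed_rank(x, y, exact_limit=25)
        assert ours.method == "wilcoxon_signed_rank_normal"
        assert ours.p_value == pytest.approx(ref, rel=1e-9)

    def test_switch_point_is_configurable(self):
        x = np.arange(30.0)
        y = x + np.linspace(1, 2, 30)
        assert (
            wilcoxon_signed_rank(x, y, exact_limit=30).method
            == "wilcoxon_signed_rank_exact"
        )


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni_adjust([0.01, 0.5], family_size=7) == [0.07, 1.0]

    def test_family_of_one_is_identity(self):
        assert bonferroni_adjust([0.3], family_size=1) == [0.3]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], family_size=2)

    def test_family_smaller_than_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], family_size=2)

    @settings(max_examples=50, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=10),
           extra=st.integers(0, 5))
    def test_never_decreases_and_preserves_order(self, ps, extra):
        adj = bonferroni_adjust(ps, family_size=len(ps) + extra)
        assert all(a >= p for a, p in zip(adj, ps))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)


def test_fisher_type_one_error_is_conservative(rng):
    """Under a true null, exact-test rejections at 0.05 stay near or below 5%."""
    n1, n2, p = 25, 30, 0.4
    reject = 0
    reps = 2000
    x = rng.binomial(n1, p, size=reps)
    y = rng.binomial(n2, p, size=reps)
    for a, c in zip(x, y):
        if fisher_exact_2x2([[a, n1 - a], [c, n2 - c]]).p_value < 0.05:
            reject += 1
    assert reject / reps <= 0.06
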