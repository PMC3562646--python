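"""Overlap percentages and the paired gene-vs-pathway level tests."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metasig.concordance import (
    compare_levels,
    overlap_percentage,
    paired_t_test,
    pairwise_overlap,
    wilcoxon_signed_rank,
)


def enumerate_signed_rank_p(d, side):
    """Exact Wilcoxon p by literal enumeration of all 2^n sign vectors."""
    d = np.asarray([v for v in d if v != 0], dtype=float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    W_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in product([1, -1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        ge += w >= W_obs - 1e-12
        le += w <= W_obs + 1e-12
    total = 2 ** n
    if side == "greater":
        return ge / total
    if side == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


class TestOverlapPercentage:
    def test_worked_example(self):
        a = [f"a{i}" for i in range(3)] + ["x", "y"]
        b = [f"b{i}" for i in range(3)] + ["x", "y"]
        assert overlap_percentage(a, b) == pytest.approx(25.0)

    def test_identical_sets_100(self):
        s = [f"g{i}" for i in range(10)]
        assert overlap_percentage(s, list(reversed(s))) == 100.0

    def test_disjoint_zero(self):
        assert overlap_percentage(["a"], ["b"]) == 0.0

    def test_empty_list_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert overlap_percentage([], ["a"]) == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_range_symmetry_extremes(self, a, b):
        if not a or not b:
            return
        a_l = [str(x) for x in a]
        b_l = [str(x) for x in b]
        p = overlap_percentage(a_l, b_l)
        assert 0.0 <= p <= 100.0
        assert p == overlap_percentage(b_l, a_l)
        assert (p == 100.0) == (a == b)
        assert (p == 0.0) == (not a & b)

    def test_shared_element_never_decreases(self, rng):
        for _ in range(50):
            a = set(map(str, rng.choice(40, size=8, replace=False)))
            b = set(map(str, rng.choice(40, size=8, replace=False)))
            before = overlap_percentage(list(a), list(b))
            a2, b2 = a | {"new"}, b | {"new"}
            assert overlap_percentage(list(a2), list(b2)) >= before


class TestPairwiseOverlap:
    def test_five_datasets_yield_ten_pairs(self):
        lists = {f"d{i}": [f"g{i}", "shared"] for i in range(5)}
        om = pairwise_overlap(lists)
        pairs, vals = om.pair_percents()
        assert len(pairs) == 10
        assert om.percent.shape == (5, 5)
        np.testing.assert_allclose(om.percent, om.percent.T)
        np.testing.assert_allclose(np.diag(om.percent), 100.0)

    def test_identical_and_disjoint(self):
        om = pairwise_overlap({"a": ["x", "y"], "b": ["y", "x"]})
        assert om.percent[0, 1] == 100.0
        om2 = pairwise_overlap({"a": ["1"], "b": ["2"], "c": ["3"]})
        off = om2.percent[~np.eye(3, dtype=bool)]
        assert (off == 0).all()

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            pairwise_overlap({"only": ["g"]})


class TestPairedT:
    def test_mean_zero_symmetric(self):
        x = np.zeros(4)
        y = np.array([3.0, -3.0, 3.0, -3.0])
        t, df, p = paired_t_test(x, y)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_constant_difference_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([0, 0, 0, 0], [1, 1, 1, 1])

    def test_matches_direct_formula(self, rng):
        x = rng.normal(0, 1, size=10)
        y = x + rng.normal(1, 1, size=10)
        t, df, p = paired_t_test(x, y)
        d = y - x
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        p_ref = 2 * stats.t.sf(abs(t_ref), 9)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_one_sided_halves_consistent(self, rng):
        x = rng.normal(0, 1, size=8)
        y = x + rng.normal(2, 0.5, size=8)
        _, _, p_two = paired_t_test(x, y, side="two")
        _, _, p_greater = paired_t_test(x, y, side="greater")
        assert p_greater == pytest.approx(p_two / 2, rel=1e-10)


class TestWilcoxon:
    def test_all_positive_n5_one_sided(self):
        x = np.zeros(5)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        W, p = wilcoxon_signed_rank(x, y, side="greater")
        assert W == 15.0
        assert p == pytest.approx(1 / 32)

    def test_antisymmetric_tied_pair(self):
        W, p = wilcoxon_signed_rank([0.0, 0.0], [2.0, -2.0])
        assert W == 1.5
        assert p == pytest.approx(1.0)

    def test_single_positive_pair(self):
        _, p = wilcoxon_signed_rank([0.0], [1.0], side="greater")
        assert p == pytest.approx(0.5)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("side", ["two", "greater", "less"])
    def test_exact_branch_equals_enumeration(self, side, rng):
        for n in range(2, 11):
            for _ in range(5):
                d = rng.normal(0.3, 1.0, size=n)
                W, p = wilcoxon_signed_rank(np.zeros(n), d, side=side)
                assert p == pytest.approx(
                    enumerate_signed_rank_p(d, side), abs=1e-12
                )

    def test_agrees_with_scipy_exact(self, rng):
        # independent cross-check of the exact branch
        d = rng.normal(0.5, 1.0, size=12)
        _, p = wilcoxon_signed_rank(np.zeros(12), d, side="two")
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-10)

    def test_approx_branch_reasonable(self, rng):
        d = rng.normal(0.5, 1.0, size=40)
        _, p = wilcoxon_signed_rank(np.zeros(40), d, side="greater")
        ref = stats.wilcoxon(
            d, method="approx", correction=True, alternative="greater"
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestCompareLevels:
    def _matrices(self, gene_lists, pathway_lists):
        return (
            pairwise_overlap(gene_lists, "gene"),
            pairwise_overlap(pathway_lists, "pathway"),
        )

    def test_all_pathway_pairs_higher_counted(self, rng):
        # genes barely overlap, pathways overlap heavily
        gl = {f"d{i}": [f"g{i}_{j}" for j in range(5 + i)] + ["shared"]
              for i in range(4)}
        pl = {f"d{i}": ["P1", "P2", "P3", f"p{i}"] for i in range(4)}
        g_om, p_om = self._matrices(gl, pl)
        cmp = compare_levels(g_om, p_om, side="greater")
        assert cmp.n_pairs == 6
        assert cmp.n_pairs_pathway_higher == 6
        assert cmp.t_p < 0.05

    def test_identical_matrices_error(self):
        lists = {"a": ["x", "q"], "b": ["x", "r"], "c": ["x", "s"]}
        g_om, p_om = self._matrices(lists, lists)
        with pytest.raises(ValueError):
            compare_levels(g_om, p_om)

    def test_mismatched_datasets_error(self):
        g_om = pairwise_overlap({"a": ["x"], "b": ["y"]}, "gene")
        p_om = pairwise_overlap({"a": ["x"], "c": ["y"]}, "pathway")
        with pytest.raises(ValueError, match="different datasets"):
            compare_levels(g_om, p_om)
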