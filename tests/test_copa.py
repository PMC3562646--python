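"""COPA transform, outlier counting, percentile pre-filter, full caller."""

import numpy as np
import pytest

from metasig.copa import (
    call_outlier_genes,
    copa_prefilter,
    copa_transform,
    count_outliers,
)
from metasig.io import CopaParams
from conftest import make_dataset


def straightline_copa(values, n_normal, cutoff, percentile):
    """Independent re-derivation of the COPA computation, plain Python.

    No code shared with the package: median/MAD from sorted lists,
    explicit loops. Returns (transformed, counts, retained_index_set).
    """
    def med(v):
        s = sorted(v)
        n = len(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0

    G, S = len(values), len(values[0])
    transformed, counts, degenerate = [], [], []
    for g in range(G):
        row = list(values[g])
        m = med(row)
        scale = 1.4826 * med([abs(v - m) for v in row])
        if scale == 0:
            degenerate.append(True)
            transformed.append([float("nan")] * S)
            counts.append(0)
            continue
        degenerate.append(False)
        trow = [(v - m) / scale for v in row]
        transformed.append(trow)
        counts.append(sum(1 for v in trow[n_normal:] if v > cutoff))
    valid = sorted(c for c, d in zip(counts, degenerate) if not d)
    import math
    k = math.ceil(percentile / 100.0 * len(valid))
    thr = valid[k - 1]
    retained = {g for g in range(G) if not degenerate[g] and counts[g] >= thr}
    return transformed, counts, degenerate, retained


class TestTransform:
    def test_hand_computed_row(self):
        # row [1,2,3,4,100]: median 3, raw MAD 1 -> value 100 maps to
        # 97 / 1.4826
        ds = make_dataset([[1, 2, 3, 4, 100.0]], n_normal=2, n_tumor=3)
        t, degenerate = copa_transform(ds)
        assert not degenerate[0]
        assert t[0, 4] == pytest.approx(97 / 1.4826, rel=1e-12)
        assert t[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_degenerate(self):
        ds = make_dataset([[5, 5, 5, 5.0], [1, 2, 3, 4.0]], n_normal=2, n_tumor=2)
        t, degenerate = copa_transform(ds)
        assert degenerate[0] and not degenerate[1]
        assert np.isnan(t[0]).all()

    def test_fixed_point_row(self):
        # a row with median 0 and scaled MAD exactly 1 transforms to itself
        raw = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        row = raw / 1.4826  # raw MAD 1/1.4826 -> scaled MAD 1
        ds = make_dataset([row], n_normal=2, n_tumor=3)
        t, _ = copa_transform(ds)
        np.testing.assert_allclose(t[0], row, rtol=1e-12)

    def test_per_gene_affine_equivariance(self, rng):
        values = rng.normal(8, 2, size=(15, 12))
        ds = make_dataset(values, n_normal=6, n_tumor=6)
        t1, _ = copa_transform(ds)
        a = rng.uniform(0.5, 3, size=(15, 1))
        b = rng.normal(0, 5, size=(15, 1))
        ds2 = make_dataset(values * a + b, n_normal=6, n_tumor=6)
        t2, _ = copa_transform(ds2)
        np.testing.assert_allclose(t2, t1, atol=1e-9)


class TestCounting:
    def test_strict_cutoff(self):
        # tumor transformed values engineered to 2.0, 1.5, 1.8
        ds = make_dataset([[0, 0, 0, 0, 2.0, 1.5, 1.8]], n_normal=4, n_tumor=3)
        t = np.array([[0, 0, 0, 0, 2.0, 1.5, 1.8]])
        counts = count_outliers(t, ds, CopaParams())
        assert counts[0] == 2

    def test_value_at_cutoff_not_counted(self):
        ds = make_dataset([[0, 0, 0, 1.7]], n_normal=3, n_tumor=1)
        t = np.array([[0, 0, 0, 1.7]])
        assert count_outliers(t, ds, CopaParams())[0] == 0

    def test_no_tumor_samples_errors(self):
        ds = make_dataset([[1, 2, 3, 4.0]], n_normal=4, n_tumor=0)
        with pytest.raises(ValueError, match="no tumor"):
            count_outliers(np.zeros((1, 4)), ds, CopaParams())

    def test_raising_cutoff_never_increases_counts(self, rng):
        values = rng.normal(0, 2, size=(30, 12))
        ds = make_dataset(values, n_normal=6, n_tumor=6)
        t, _ = copa_transform(ds)
        prev = count_outliers(t, ds, CopaParams(outlier_cutoff=1.0))
        for cut in (1.5, 1.7, 2.5):
            cur = count_outliers(t, ds, CopaParams(outlier_cutoff=cut))
            assert np.all(cur <= prev)
            prev = cur


class TestPrefilter:
    def test_nearest_rank_example(self):
        counts = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 5])
        genes = [f"g{i}" for i in range(10)]
        retained, thr = copa_prefilter(counts, genes, np.zeros(10, bool), 95)
        assert thr == 5
        assert retained == ["g9"]

    def test_all_equal_counts_all_retained(self):
        counts = np.full(8, 3)
        genes = [f"g{i}" for i in range(8)]
        retained, thr = copa_prefilter(counts, genes, np.zeros(8, bool), 95)
        assert thr == 3 and len(retained) == 8

    def test_percentile_100_keeps_max_ties_only(self):
        counts = np.array([1, 4, 4, 2])
        genes = ["a", "b", "c", "d"]
        retained, thr = copa_prefilter(counts, genes, np.zeros(4, bool), 100)
        assert thr == 4 and set(retained) == {"b", "c"}

    def test_raising_percentile_never_grows_retained_set(self, rng):
        counts = rng.integers(0, 6, size=40)
        genes = [f"g{i}" for i in range(40)]
        prev = None
        for pct in (50, 75, 90, 95, 100):
            retained, _ = copa_prefilter(counts, genes, np.zeros(40, bool), pct)
            if prev is not None:
                assert set(retained) <= prev
            prev = set(retained)

    def test_invalid_percentile_errors(self):
        with pytest.raises(ValueError):
            copa_prefilter(np.array([1]), ["g"], np.zeros(1, bool), 0)


class TestFullCall:
    def test_matches_straightline_oracle(self, rng):
        for _ in range(10):
            values = rng.normal(0, 1, size=(30, 12))
            ds = make_dataset(values, n_normal=6, n_tumor=6)
            res = call_outlier_genes(ds, CopaParams())
            t_o, c_o, deg_o, ret_o = straightline_copa(
                values.tolist(), 6, 1.7, 95
            )
            ok = ~res.degenerate
            np.testing.assert_allclose(
                res.transformed[ok], np.array(t_o)[ok], atol=1e-10
            )
            assert list(res.outlier_counts[ok]) == [
                c for c, d in zip(c_o, deg_o) if not d
            ]
            assert {ds.genes.index(g) for g in res.retained_genes} == ret_o

    def test_planted_outlier_gene_retained(self, rng):
        G, n_n, n_t = 201, 10, 10
        values = rng.normal(8, 1, size=(G, n_n + n_t))
        # gene 0 overexpressed by +5 log2 in 40% of tumors
        values[0, n_n:n_n + 4] += 5.0
        ds = make_dataset(values, n_normal=n_n, n_tumor=n_t)
        res = call_outlier_genes(ds)
        assert "g1" in res.retained_genes

    def test_deterministic(self, rng):
        values = rng.normal(0, 1, size=(25, 10))
        ds = make_dataset(values, n_normal=5, n_tumor=5)
        r1 = call_outlier_genes(ds)
        r2 = call_outlier_genes(ds)
        assert r1.retained_genes == r2.retained_genes
        np.testing.assert_array_equal(r1.outlier_counts, r2.outlier_counts)
        np.testing.assert_allclose(
            r1.transformed, r2.transformed, equal_nan=True
        )

    def test_two_sided_flag_counts_underexpression(self):
        row = [0, 1, 2, 3, 4, 5, 6, 7, -50.0, 50.0]
        ds = make_dataset([row, list(np.arange(10.0))], n_normal=5, n_tumor=5)
        res1 = call_outlier_genes(ds, CopaParams())
        res2 = call_outlier_genes(ds, CopaParams(two_sided=True))
        assert res2.outlier_counts[0] == res1.outlier_counts[0] + 1
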