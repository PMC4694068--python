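"""Induction rescaling, Spearman correlograms, profile clustering."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from senescreen.profiles import (
    cluster_profiles,
    log2_matrix,
    scale_induction,
    scale_matrix,
    spearman_matrix,
)


def brute_spearman(x, y):
    """Independent oracle: explicit midranks + explicit Pearson formula."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestScaleInduction:
    def test_anchor_points(self):
        s = scale_induction([1.0, 3.0, 5.0])
        assert np.allclose(s, [0.0, 0.5, 1.0])

    def test_degenerate_no_induction_column(self):
        assert np.allclose(scale_induction([0.5, 1.0]), [0.0, 0.0])

    def test_clipping_below_one_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            s = scale_induction([0.5, 1.0, 2.0])
        assert np.allclose(s, [0.0, 0.0, 1.0])

    def test_order_preserving_and_max_maps_to_one(self, rng):
        x = np.exp(rng.normal(0, 1, 50))
        x[0] = x.max() + 1.0
        s = scale_induction(x)
        assert s[np.argmax(x)] == 1.0
        pos = x > 1
        order = np.argsort(x[pos])
        assert (np.diff(s[pos][order]) >= 0).all()

    def test_nonpositive_is_hard_error(self):
        with pytest.raises(ValueError):
            scale_induction([1.0, 0.0])


def test_log2_matrix_examples():
    fc = pd.DataFrame({"G": [1.0, 100.0, 0.25]}, index=["CTRL", "K1", "K2"])
    m = log2_matrix(fc)
    assert m.loc["CTRL", "G"] == 0.0
    assert m.loc["K1", "G"] == pytest.approx(math.log2(100), rel=1e-12)
    assert m.loc["K2", "G"] == -2.0


class TestSpearman:
    def test_self_and_anti_correlation(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        m = pd.DataFrame({"a": x, "b": x, "c": [-v for v in x]})
        res = spearman_matrix(m)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert res.p.loc["a", "b"] == 0.0

    def test_known_small_example(self):
        # oracle: midrank Pearson of (1..5) vs (2,1,4,3,5) = 1 - 6*4/120 = 0.8
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        assert brute_spearman(x, y) == pytest.approx(0.8, abs=1e-15)
        m = pd.DataFrame({"x": x, "y": y})
        assert spearman_matrix(m).rho.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        vals = rng.integers(0, 4, size=(12, 3)).astype(float)  # heavy ties
        m = pd.DataFrame(vals, columns=["a", "b", "c"])
        res = spearman_matrix(m)
        for i, j in itertools.combinations(m.columns, 2):
            assert res.rho.loc[i, j] == pytest.approx(
                brute_spearman(m[i], m[j]), abs=1e-12
            )

    def test_rank_invariance_under_monotone_transform(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        m2 = m.assign(a=np.exp(m["a"]))
        r1 = spearman_matrix(m).rho
        r2 = spearman_matrix(m2).rho
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_t_approximation_p_value(self):
        # n=5, rho=0.8 → t = 0.8*sqrt(3/0.36), p = 2*sf(t, 3)
        from scipy import stats

        m = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        res = spearman_matrix(m)
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        assert res.p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(t, 3), rel=1e-9)
        assert res.p.loc["x", "x"] == 1.0  # diagonal convention

    def test_exact_permutation_p_tiny_n(self):
        # perfect monotone triple: 2 of 3! permutations reach |rho| = 1
        m = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [10.0, 20.0, 30.0]})
        res = spearman_matrix(m, p_mode="exact")
        assert res.p.loc["x", "y"] == pytest.approx(2 / 6)
        with pytest.raises(ValueError, match="exact"):
            spearman_matrix(pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)),
                                         columns=["x", "y"]), p_mode="exact")

    def test_constant_column_is_nan_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_matrix(m)
        assert np.isnan(res.rho.loc["a", "b"])
        assert res.rho.loc["b", "b"] == 1.0

    def test_symmetry_and_unit_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = spearman_matrix(m)
        r = res.rho.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert ((res.p.to_numpy() >= 0) & (res.p.to_numpy() <= 1)).all()


class TestClustering:
    def test_identical_columns_merge_first_at_height_zero(self, rng):
        base = rng.normal(size=20)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=20), "d": rng.normal(size=20)}
        )
        dendro = cluster_profiles(m)
        a, b, height, size = dendro.merges[0]
        assert {dendro.labels[a], dendro.labels[b]} == {"a", "b"}
        assert height == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    def test_first_merge_joins_most_correlated_pair(self, rng):
        # construct 3 columns with pairwise rho ~ (0.9, ~0, ~0)
        n = 200
        shared = rng.normal(size=n)
        a = shared + 0.3 * rng.normal(size=n)
        b = shared + 0.3 * rng.normal(size=n)
        c = rng.normal(size=n)
        dendro = cluster_profiles(pd.DataFrame({"a": a, "b": b, "c": c}))
        i, j, _, _ = dendro.merges[0]
        assert {dendro.labels[i], dendro.labels[j]} == {"a", "b"}

    def test_heights_nondecreasing_and_bounded(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        dendro = cluster_profiles(m)
        heights = [h for _, _, h, _ in dendro.merges]
        assert all(0.0 <= h <= 2.0 + 1e-12 for h in heights)
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        assert len(dendro.merges) == m.shape[1] - 1

    def test_constant_column_is_hard_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cluster_profiles(m)

    def test_newick_round_trips_through_a_tree_parser(self, rng):
        import skbio

        m = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("vwxyz"))
        dendro = cluster_profiles(m)
        nwk = dendro.to_newick()
        tree = skbio.TreeNode.read([nwk])
        assert {t.name for t in tree.tips()} == set("vwxyz")
        assert set(dendro.leaf_order) == set("vwxyz")


def test_scale_matrix_columnwise(rng):
    fc = pd.DataFrame(
        {"g1": [1.0, 2.0, 5.0], "g2": [1.0, 1.0, 1.0]}, index=["CTRL", "K1", "K2"]
    )
    s = scale_matrix(fc)
    assert np.allclose(s["g1"], [0.0, 0.25, 1.0])
    assert np.allclose(s["g2"], 0.0)
    assert s.attrs["representation"] == "scaled01"
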