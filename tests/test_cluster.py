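"""Pearson distance, WPGMA linkage (with a hand-traced oracle), heatmap export."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from kinopipe.cluster import (
    Dendrogram,
    heatmap_export,
    pearson_distance_matrix,
    wpgma_cluster,
)


def _dist_frame(mat, labels):
    return pd.DataFrame(np.asarray(mat, float), index=labels, columns=labels)


class TestPearsonDistance:
    def test_self_distance_zero_and_negation_two(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        prof = pd.DataFrame([x, x, -x], index=["a", "b", "neg"])
        d = pearson_distance_matrix(prof)
        assert d.loc["a", "a"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["a", "neg"] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        prof = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        d = pearson_distance_matrix(prof)
        for i in range(4):
            for j in range(4):
                x, y = prof.iloc[i].to_numpy(), prof.iloc[j].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                r = (xc * yc).sum() / (
                    len(x) * x.std() * y.std()
                )
                assert d.iloc[i, j] == pytest.approx(1.0 - r, abs=1e-12)

    def test_properties(self, rng):
        prof = pd.DataFrame(rng.normal(size=(8, 20)))
        d = pearson_distance_matrix(prof).to_numpy()
        assert (d >= 0).all() and (d <= 2).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_zero_variance_item_named_in_error(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance_matrix(prof)


# Hand-executed WPGMA trace for the 5-leaf matrix below:
#   step 1: min is d(a,b)=2        -> node 5 at height 2
#            d(ab,c)=(5+4)/2=4.5  d(ab,d)=(9+7)/2=8  d(ab,e)=(8+6)/2=7
#   step 2: min is d(d,e)=3        -> node 6 at height 3
#            d(de,c)=(6+5)/2=5.5  d(de,ab)=(8+7)/2=7.5
#   step 3: min is d(ab,c)=4.5     -> node 7 at height 4.5
#            d(abc,de)=(7.5+5.5)/2=6.5
#   step 4: final merge at 6.5     -> node 8
HAND_MATRIX = [
    [0, 2, 5, 9, 8],
    [2, 0, 4, 7, 6],
    [5, 4, 0, 6, 5],
    [9, 7, 6, 0, 3],
    [8, 6, 5, 3, 0],
]
HAND_TRACE = ((0, 1, 2.0), (3, 4, 3.0), (2, 5, 4.5), (6, 7, 6.5))


class TestWpgma:
    def test_two_leaves(self):
        tree = wpgma_cluster(_dist_frame([[0, 3], [3, 0]], ["a", "b"]))
        assert tree.merges == ((0, 1, 3.0),)
        assert tree.leaf_order() == ["a", "b"]

    def test_five_leaf_hand_oracle(self):
        tree = wpgma_cluster(_dist_frame(HAND_MATRIX, list("abcde")))
        assert tree.merges == HAND_TRACE

    def test_equal_distances_merge_left_to_right(self):
        n = 4
        d = np.full((n, n), 1.5)
        np.fill_diagonal(d, 0.0)
        tree = wpgma_cluster(_dist_frame(d, list("abcd")))
        assert tree.merges == ((0, 1, 1.5), (2, 3, 1.5), (4, 5, 1.5))

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            wpgma_cluster(_dist_frame(d, ["a", "b"]))

    def test_heights_match_scipy_weighted_linkage(self, rng):
        # tie-free random distances: merge heights must agree with the
        # reference WPGMA ("weighted"/McQuitty) implementation
        for _ in range(5):
            n = 7
            pts = rng.normal(size=(n, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = wpgma_cluster(_dist_frame(d, [f"i{i}" for i in range(n)]))
            ref = linkage(squareform(d, checks=False), method="weighted")
            np.testing.assert_allclose(sorted(tree.heights), sorted(ref[:, 2]),
                                       rtol=1e-10)

    def test_permutation_invariant_heights(self, rng):
        n = 6
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"i{i}" for i in range(n)]
        tree = wpgma_cluster(_dist_frame(d, labels))
        perm = rng.permutation(n)
        tree_p = wpgma_cluster(
            _dist_frame(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        )
        np.testing.assert_allclose(sorted(tree.heights), sorted(tree_p.heights),
                                   rtol=1e-12)

    def test_heights_nondecreasing(self, rng):
        pts = rng.normal(size=(9, 5))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = wpgma_cluster(_dist_frame(d, [f"i{i}" for i in range(9)]))
        heights = np.array(tree.heights)
        # WPGMA on a metric matrix: merge heights grow monotonically
        assert (np.diff(heights) >= -1e-12).all()


class TestNewickAndHeatmap:
    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        tree = wpgma_cluster(_dist_frame(HAND_MATRIX, list("abcde")))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("abcde")
        # ultrametric: all root-to-leaf path lengths equal root height / 2
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(depths, 6.5 / 2.0)

    def test_export_orders_match_trees_and_round_trip(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(6, 5)),
            index=[f"r{i}" for i in range(6)],
            columns=[f"c{i}" for i in range(5)],
        )
        row_tree = wpgma_cluster(pearson_distance_matrix(mat))
        col_tree = wpgma_cluster(pearson_distance_matrix(mat.T))
        export = heatmap_export(mat, row_tree, col_tree)
        assert list(export["matrix"].index) == row_tree.leaf_order()
        assert list(export["matrix"].columns) == col_tree.leaf_order()
        # serialization round trip
        buf = io.StringIO()
        export["matrix"].to_csv(buf, sep="\t")
        buf.seek(0)
        back = pd.read_csv(buf, sep="\t", index_col=0)
        pd.testing.assert_frame_equal(back, export["matrix"])

    def test_dimension_mismatch_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 4)))
        tree = wpgma_cluster(pearson_distance_matrix(mat))
        wrong = Dendrogram(labels=("x", "y"), merges=((0, 1, 1.0),))
        with pytest.raises(ValueError, match="do not match"):
            heatmap_export(mat, wrong, tree)
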