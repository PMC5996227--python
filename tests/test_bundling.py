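"""Edge similarity, UPGMA, inconsistency coefficient and tree cutting."""
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from hyperbundle import bundling
from hyperbundle.mixing_properties import MixingProperties, edge_fidelity

from conftest import merge_sets, random_distance_matrix, upgma_bruteforce


def _props_from_matrix(m):
    n = m.shape[0]
    fp = np.ones(n)
    return MixingProperties(
        f_mix=m, plv0=m, f_p=fp, f_e=edge_fidelity(fp), n_iterations=1, n_samples=1000
    )


class TestEdgeSimilarity:
    def test_self_similarity_is_one(self):
        m = 0.2 * np.ones((4, 4))
        sim = bundling.edge_similarity([(0, 1), (2, 3)], _props_from_matrix(m))
        np.testing.assert_allclose(np.diag(sim.S), 1.0)

    def test_pairing_max_of_geometric_means(self):
        m = np.array(
            [
                [1.0, 0.10, 0.30, 0.20],
                [0.10, 1.0, 0.40, 0.60],
                [0.30, 0.40, 1.0, 0.05],
                [0.20, 0.60, 0.05, 1.0],
            ]
        )
        sim = bundling.edge_similarity([(0, 1), (2, 3)], _props_from_matrix(m))
        expected = max(np.sqrt(0.30 * 0.60), np.sqrt(0.20 * 0.40))
        assert sim.S[0, 1] == pytest.approx(expected)

    def test_unmixed_edges_near_zero(self):
        m = 1e-4 * np.ones((4, 4))
        sim = bundling.edge_similarity([(0, 1), (2, 3)], _props_from_matrix(m))
        assert sim.S[0, 1] < 0.01

    def test_unknown_parcel_rejected(self):
        m = 0.2 * np.ones((3, 3))
        with pytest.raises(ValueError):
            bundling.edge_similarity([(0, 5)], _props_from_matrix(m))

    def test_kin_edges_more_similar_than_far(self, grid_exp, grid_props):
        sim = bundling.edge_similarity(grid_exp.true_edges, grid_props)
        idx = {e: k for k, e in enumerate(grid_exp.true_edges)}
        kin = grid_exp.edge_groups["kin"]
        far = grid_exp.edge_groups["far"]
        s_kin = sim.S[idx[kin[0]], idx[kin[1]]]
        s_far = sim.S[idx[far[0]], idx[far[1]]]
        assert s_kin > s_far


class TestUpgma:
    def test_two_leaves(self):
        tree = bundling.upgma(np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.4)

    def test_first_merge_is_global_minimum(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.3, 1.0, size=(5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d[1, 3] = d[3, 1] = 0.17
        tree = bundling.upgma(d)
        assert tuple(tree.linkage[0, :2]) == (1.0, 3.0)
        assert tree.linkage[0, 2] == pytest.approx(0.17)

    @pytest.mark.parametrize("n", [4, 7, 10, 15])
    def test_agrees_with_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = random_distance_matrix(n, rng)
            tree = bundling.upgma(d)
            oracle = upgma_bruteforce(d)
            np.testing.assert_array_equal(tree.linkage[:, :2], oracle[:, :2])
            np.testing.assert_allclose(tree.linkage[:, 2], oracle[:, 2], rtol=1e-10)
            np.testing.assert_array_equal(tree.linkage[:, 3], oracle[:, 3])

    def test_agrees_with_scipy_average_linkage(self):
        # independent cross-check against the reference implementation
        rng = np.random.default_rng(99)
        for _ in range(10):
            d = random_distance_matrix(12, rng)
            ours = bundling.upgma(d)
            ref = scipy_linkage(squareform(d), method="average")
            np.testing.assert_allclose(np.sort(ours.heights), np.sort(ref[:, 2]))
            assert merge_sets(ours.linkage, 12) == merge_sets(ref, 12)

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        tree = bundling.upgma(random_distance_matrix(20, rng))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            bundling.upgma(d)


def _manual_tree():
    """5-leaf tree with merge heights u=0.17, w=0.25, v=0.22, h=0.361.

    Leaves: a=0, b=1, e=2, c=3, d=4.  u=(a,b); v=(u,e); w=(c,d); h=(v,w).
    Within depth 2 below h the heights are {h, v, w}, mean 0.277; within
    depth 3 they are {h, v, w, u}, mean ~0.25.
    """
    linkage = np.array(
        [
            [0, 1, 0.17, 2],  # u -> id 5
            [3, 4, 0.25, 2],  # w -> id 6
            [2, 5, 0.22, 3],  # v -> id 7
            [6, 7, 0.361, 5],  # h -> id 8
        ]
    )
    return bundling.HyperedgeTree(linkage=linkage, n_leaves=5)


class TestInconsistency:
    def test_depth_two_neighbourhood_mean(self):
        tree = _manual_tree()
        kappa = bundling.inconsistency(tree, theta=2)
        heights = np.array([0.361, 0.22, 0.25])
        assert heights.mean() == pytest.approx(0.277)
        expected = (0.361 - heights.mean()) / heights.std(ddof=1)
        assert kappa[3] == pytest.approx(expected)

    def test_depth_three_includes_grandchildren(self):
        tree = _manual_tree()
        kappa = bundling.inconsistency(tree, theta=3)
        heights = np.array([0.361, 0.22, 0.25, 0.17])
        expected = (0.361 - heights.mean()) / heights.std(ddof=1)
        assert kappa[3] == pytest.approx(expected)

    def test_bottom_ties_are_zero(self):
        tree = _manual_tree()
        kappa = bundling.inconsistency(tree, theta=2)
        assert kappa[0] == 0.0  # u: both children leaves
        assert kappa[1] == 0.0  # w: both children leaves

    def test_four_leaf_hand_computation(self):
        linkage = np.array(
            [[0, 1, 0.1, 2], [2, 3, 0.3, 2], [4, 5, 0.8, 4]]
        )
        tree = bundling.HyperedgeTree(linkage=linkage, n_leaves=4)
        kappa = bundling.inconsistency(tree, theta=2)
        hs = np.array([0.8, 0.1, 0.3])
        assert kappa[2] == pytest.approx((0.8 - hs.mean()) / hs.std(ddof=1))
        assert kappa[0] == kappa[1] == 0.0


class TestCutTree:
    def test_uniform_distances_single_hyperedge(self):
        d = 0.5 * (1 - np.eye(6))
        tree = bundling.upgma(d)
        part = bundling.cut_tree(tree, cl=0.15)
        assert len(part) == 1
        assert part.hyperedges[0] == frozenset(range(6))

    def test_cl_one_all_singletons(self):
        rng = np.random.default_rng(2)
        tree = bundling.upgma(random_distance_matrix(8, rng))
        part = bundling.cut_tree(tree, cl=1.0)
        assert len(part) == 8

    def test_subtree_below_threshold_stays_intact(self):
        # two tight blocks far apart: the only high-kappa merge is the root
        d = np.full((6, 6), 0.9)
        for blk in (slice(0, 3), slice(3, 6)):
            d[blk, blk] = 0.1
        np.fill_diagonal(d, 0.0)
        tree = bundling.upgma(d)
        part = bundling.cut_tree(tree, cl=0.3)
        assert frozenset([0, 1, 2]) in part.hyperedges
        assert frozenset([3, 4, 5]) in part.hyperedges

    def test_hyperedge_count_monotone_in_cl(self):
        rng = np.random.default_rng(3)
        tree = bundling.upgma(random_distance_matrix(25, rng))
        counts = [
            len(bundling.cut_tree(tree, cl=cl))
            for cl in (0.05, 0.15, 0.3, 0.5, 0.8, 1.0)
        ]
        assert counts == sorted(counts)

    def test_invalid_cl(self):
        tree = _manual_tree()
        with pytest.raises(ValueError):
            bundling.cut_tree(tree, cl=0.0)


class TestBundle:
    def test_single_edge_graph(self, grid_props):
        part = bundling.bundle([(0, 1)], grid_props)
        assert len(part) == 1 and part.hyperedges[0] == frozenset([0])

    def test_partition_covers_all_edges_disjointly(self, grid_exp, grid_props):
        part = bundling.bundle(grid_exp.edges, grid_props)
        labels = part.labels()  # would raise if not a disjoint cover
        assert labels.shape == (len(grid_exp.edges),)

    def test_far_edges_bundled_apart_from_kin(self, grid_exp, grid_props):
        part = bundling.bundle(grid_exp.edges, grid_props, cl=0.15)
        idx = {e: k for k, e in enumerate(grid_exp.edges)}
        labels = part.labels()
        far_labels = {labels[idx[e]] for e in grid_exp.edge_groups["far"]}
        kin_labels = {labels[idx[e]] for e in grid_exp.edge_groups["kin"]}
        assert far_labels.isdisjoint(kin_labels)
        # and the two far edges are mutually apart as well
        assert len(far_labels) == 2

    def test_each_true_interaction_in_own_hyperedge(self, grid_exp, grid_props):
        part = bundling.bundle(grid_exp.edges, grid_props, cl=0.15)
        idx = {e: k for k, e in enumerate(grid_exp.edges)}
        labels = part.labels()
        true_labels = [labels[idx[e]] for e in grid_exp.true_edges if e in idx]
        assert len(true_labels) == 6
        assert len(set(true_labels)) == 6

    def test_bundles_far_fewer_hyperedges_than_edges(self, grid_exp, grid_props):
        part = bundling.bundle(grid_exp.edges, grid_props, cl=0.15)
        assert 6 <= len(part) < len(grid_exp.edges) / 2
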