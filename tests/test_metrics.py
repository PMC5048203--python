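"""Weighted graph metrics against brute-force oracles; null-model contract."""

import itertools

import numpy as np
import pytest

import strucnet as sn

from conftest import make_connectome, random_connectome


def brute_force_clustering(w):
    """Onnela coefficient by explicit triple enumeration."""
    w = w.astype(float)
    n = len(w)
    what = w / w.max() if w.max() > 0 else w
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i:
                    continue
                total += (what[i, j] * what[i, h] * what[j, h]) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return c


def brute_force_shortest_paths(w):
    """All-pairs shortest 1/w path lengths by Floyd-Warshall."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


class TestNodalStrength:
    def test_uniform_triangle(self):
        w = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        np.testing.assert_array_equal(sn.nodal_strength(make_connectome(w)), [4, 4, 4])

    def test_isolated_node_zero(self):
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 3
        s = sn.nodal_strength(make_connectome(w))
        assert s[2] == s[3] == 0

    def test_matches_row_sums(self):
        c = random_connectome(10, 0.5, np.random.default_rng(2))
        np.testing.assert_array_equal(sn.nodal_strength(c), c.weights.sum(1))


class TestWeightedClustering:
    def test_uniform_triangle_is_one(self):
        w = np.array([[0, 7, 7], [7, 0, 7], [7, 7, 0]])
        np.testing.assert_allclose(sn.weighted_clustering(make_connectome(w)), 1.0)

    def test_star_is_zero(self):
        w = np.zeros((5, 5), dtype=int)
        w[0, 1:] = w[1:, 0] = 4
        np.testing.assert_array_equal(sn.weighted_clustering(make_connectome(w)), 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            c = random_connectome(12, 0.45, rng)
            np.testing.assert_allclose(
                sn.weighted_clustering(c), brute_force_clustering(c.weights),
                atol=1e-12,
            )

    def test_matches_networkx_onnela(self):
        """Independent toolbox cross-check of the Onnela convention."""
        import networkx as nx

        rng = np.random.default_rng(6)
        c = random_connectome(12, 0.5, rng)
        g = nx.from_numpy_array(c.weights.astype(float))
        expected = np.array([nx.clustering(g, weight="weight")[i] for i in range(12)])
        np.testing.assert_allclose(sn.weighted_clustering(c), expected, atol=1e-12)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            c = random_connectome(10, 0.6, rng)
            cl = sn.weighted_clustering(c)
            assert ((cl >= 0) & (cl <= 1 + 1e-12)).all()


class TestWeightedDistances:
    def test_unit_chain(self):
        w = np.zeros((3, 3), dtype=int)
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1
        d = sn.weighted_distances(make_connectome(w))
        assert d[0, 2] == pytest.approx(2.0)

    def test_detour_beats_direct_edge(self):
        """Chain weights 2 and 4 (length 0.75) beat the direct weight 1."""
        w = np.zeros((3, 3), dtype=int)
        w[0, 1] = w[1, 0] = 2
        w[1, 2] = w[2, 1] = 4
        w[0, 2] = w[2, 0] = 1
        d = sn.weighted_distances(make_connectome(w))
        assert d[0, 2] == pytest.approx(0.75)

    def test_disconnected_pair_infinite(self):
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 2
        d = sn.weighted_distances(make_connectome(w))
        assert np.isinf(d[0, 3])

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            c = random_connectome(12, 0.35, rng)
            np.testing.assert_allclose(
                sn.weighted_distances(c),
                brute_force_shortest_paths(c.weights), atol=1e-12,
            )


class TestCharPathLength:
    def test_complete_unit_graph(self):
        w = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        gl, per_node = sn.char_path_length(make_connectome(w))
        assert gl == pytest.approx(1.0)
        np.testing.assert_allclose(per_node, 1.0)

    def test_path_graph_matches_enumeration(self):
        w = np.zeros((4, 4), dtype=int)
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1
        gl, _ = sn.char_path_length(make_connectome(w))
        # distances: 1,2,3,1,2,1 over 6 unordered pairs
        assert gl == pytest.approx((1 + 2 + 3 + 1 + 2 + 1) / 6)

    def test_adding_edge_never_increases_length(self):
        rng = np.random.default_rng(10)
        c = random_connectome(10, 0.4, rng)
        gl0, _ = sn.char_path_length(c)
        w = c.weights.copy()
        empty = np.argwhere(np.triu(w == 0, k=1))
        i, j = empty[0]
        w[i, j] = w[j, i] = 30
        gl1, _ = sn.char_path_length(make_connectome(w))
        assert gl1 <= gl0 + 1e-12

    def test_unreachable_pairs_warn(self):
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 2
        with pytest.warns(UserWarning, match="unreachable"):
            sn.char_path_length(make_connectome(w))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            sn.char_path_length(make_connectome(np.zeros((4, 4), dtype=int)))


class TestGlobalSummaries:
    def test_triangle_identity(self):
        w = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        gs, tf = sn.global_summaries(make_connectome(w))
        assert (gs, tf) == (4.0, 6.0)
        assert gs * 3 / 2 == tf

    def test_identity_holds_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            c = random_connectome(n, 0.4, rng)
            gs, tf = sn.global_summaries(c)
            assert gs * n / 2 == pytest.approx(tf, rel=1e-12)

    def test_zero_graph(self):
        assert sn.global_summaries(make_connectome(np.zeros((5, 5), dtype=int))) == (0.0, 0.0)


class TestRewiring:
    def test_degree_sequence_and_weight_multiset_preserved(self):
        rng = np.random.default_rng(13)
        for k in range(50):
            n = int(rng.integers(6, 20))
            c = random_connectome(n, 0.4, rng)
            r = sn.rewire_preserving_degree(c, seed=k)
            np.testing.assert_array_equal(
                (c.weights > 0).sum(1), (r.weights > 0).sum(1)
            )
            iu = np.triu_indices(n, k=1)
            np.testing.assert_array_equal(
                np.sort(c.weights[iu][c.weights[iu] > 0]),
                np.sort(r.weights[iu][r.weights[iu] > 0]),
            )

    def test_too_small_graph_returns_copy_with_warning(self):
        w = np.zeros((3, 3), dtype=int)
        w[0, 1] = w[1, 0] = 5
        c = make_connectome(w)
        with pytest.warns(UserWarning, match="too small"):
            r = sn.rewire_preserving_degree(c, seed=0)
        np.testing.assert_array_equal(r.weights, c.weights)

    def test_mixing_distributes_weights_over_cycle_positions(self):
        """On a 4-cycle with distinct weights, each weight visits every
        position of the (relabeled) cycle approximately uniformly."""
        w = np.zeros((4, 4), dtype=int)
        cycle = [(0, 1, 10), (1, 2, 20), (2, 3, 30), (3, 0, 40)]
        for i, j, v in cycle:
            w[i, j] = w[j, i] = v
        c = make_connectome(w)
        counts = {}
        n_rep = 600
        for k in range(n_rep):
            r = sn.rewire_preserving_degree(c, swaps_per_edge=20, seed=k)
            counts[r.weights[0, 1]] = counts.get(r.weights[0, 1], 0) + 1
        # a 4-cycle rewires onto 3 perfect matching pairings of the weights;
        # the weight on edge (0,1) should not be stuck at its original value
        assert len(counts) >= 3
        assert max(counts.values()) < 0.6 * n_rep


class TestSmallWorldNormalization:
    def test_self_normalization_near_unity(self):
        """A degree-matched random draw normalizes to gamma ~ 1, lambda ~ 1."""
        spec = sn.CohortSpec(n_a=2, n_b=2, n_nodes=40, density=0.3, seed=17,
                             effect=None)
        base = sn.sample_cohort(spec).group_a[0]
        observed = sn.rewire_preserving_degree(base, seed=99)
        gamma, lam = sn.normalized_small_world(observed, n_random=150, seed=1)
        assert gamma == pytest.approx(1.0, abs=0.1)
        assert lam == pytest.approx(1.0, abs=0.1)

    def test_modular_template_is_small_world(self):
        """The modular cohort template lands in the small-world regime."""
        spec = sn.CohortSpec(n_a=2, n_b=2, n_nodes=83, density=0.25, seed=19,
                             effect=None)
        c = sn.sample_cohort(spec).group_a[0]
        gamma, lam = sn.normalized_small_world(c, n_random=60, seed=2)
        assert gamma > 1.0
        assert lam == pytest.approx(1.0, abs=0.25)

    def test_seed_invariance_within_monte_carlo_error(self):
        spec = sn.CohortSpec(n_a=2, n_b=2, n_nodes=30, density=0.3, seed=23,
                             effect=None)
        c = sn.sample_cohort(spec).group_a[0]
        gammas, lams = [], []
        for seed in range(5):
            g, l = sn.normalized_small_world(c, n_random=80, seed=seed)
            gammas.append(g)
            lams.append(l)
        assert np.ptp(gammas) < 0.1
        assert np.ptp(lams) < 0.1


class TestScalingInvariances:
    def test_uniform_rescaling_preserves_clustering_and_lambda(self):
        rng = np.random.default_rng(29)
        c = random_connectome(15, 0.4, rng)
        scaled = make_connectome(c.weights * 3)
        np.testing.assert_allclose(
            sn.weighted_clustering(c), sn.weighted_clustering(scaled), atol=1e-12
        )
        d1 = sn.weighted_distances(c)
        d3 = sn.weighted_distances(scaled)
        finite = np.isfinite(d1)
        np.testing.assert_allclose(d1[finite], 3 * d3[finite], rtol=1e-12)
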