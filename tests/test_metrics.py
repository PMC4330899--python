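import numpy as np
import pytest

from connrel.metrics import (
    NullEnsembleConfig,
    char_path_length,
    clustering_coefficient,
    global_efficiency,
    global_metrics,
    local_efficiency,
    nodal_efficiency,
    nodal_strength,
    rewire_null,
    shortest_distances,
    small_world,
)
from connrel.netbuild import binarize

from _oracles import (
    brute_binary_clustering,
    brute_char_path_length,
    brute_distances,
    brute_global_efficiency,
    brute_nodal_efficiency,
)
from conftest import matrix_from_edges, random_weighted_graph


class TestNodalStrength:
    def test_worked_examples(self, triangle, star4, four_node):
        assert np.array_equal(nodal_strength(triangle), [2, 2, 2])
        assert np.array_equal(nodal_strength(star4), [3, 1, 1, 1])
        assert np.array_equal(nodal_strength(four_node), [6, 6, 7, 1])


class TestDistances:
    def test_unit_path_and_reciprocal_lengths(self, path3):
        d = shortest_distances(path3)
        assert d[0, 2] == 2.0
        m = matrix_from_edges(2, {(0, 1): 4})
        assert shortest_distances(m)[0, 1] == 0.25

    def test_disconnected_pairs_are_infinite(self):
        m = matrix_from_edges(4, {(0, 1): 1, (2, 3): 1})
        d = shortest_distances(m)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_strong_detour_beats_weak_direct_edge(self):
        m = matrix_from_edges(3, {(0, 1): 10, (1, 2): 10, (0, 2): 1})
        assert shortest_distances(m)[0, 2] == pytest.approx(0.2)


class TestEfficiencyAndPathLength:
    def test_triangle(self, triangle):
        assert global_efficiency(triangle) == pytest.approx(1.0)
        assert char_path_length(triangle) == pytest.approx(1.0)

    def test_unit_path(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)
        assert char_path_length(path3) == pytest.approx(4 / 3)

    def test_partially_disconnected(self):
        m = matrix_from_edges(3, {(0, 1): 1})
        assert global_efficiency(m) == pytest.approx(1 / 3)
        assert char_path_length(m) == pytest.approx(1.0)  # connected pairs only

    def test_edgeless_graph_flagged_not_raised(self):
        m = matrix_from_edges(3, {})
        assert global_efficiency(m) == 0.0
        assert np.isnan(char_path_length(m))


class TestClustering:
    def test_triangle_and_star(self, triangle, star4):
        assert clustering_coefficient(triangle) == pytest.approx(1.0)
        assert clustering_coefficient(star4) == 0.0

    def test_binary_input_matches_triangle_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = (random_weighted_graph(6, 0.5, rng) > 0).astype(float)
            assert clustering_coefficient(w) == pytest.approx(
                brute_binary_clustering(w), abs=1e-12
            )

    def test_raw_variant_scales_with_weights(self, triangle):
        scaled = triangle.copy()
        scaled.weights = scaled.weights * 5
        assert clustering_coefficient(scaled, normalize_weights=False) == pytest.approx(5.0)
        assert clustering_coefficient(scaled, normalize_weights=True) == pytest.approx(1.0)


class TestLocalEfficiency:
    def test_triangle_and_star(self, triangle, star4):
        assert local_efficiency(triangle) == pytest.approx(1.0)
        assert local_efficiency(star4) == 0.0

    def test_triangle_with_pendant_matches_brute_force(self):
        m = matrix_from_edges(4, {(0, 1): 1, (0, 2): 1, (1, 2): 1, (2, 3): 1})
        w = m.weights
        expected = []
        for i in range(4):
            nbrs = np.nonzero(w[i])[0]
            if len(nbrs) < 2:
                expected.append(0.0)
            else:
                expected.append(brute_global_efficiency(w[np.ix_(nbrs, nbrs)]))
        assert local_efficiency(m) == pytest.approx(np.mean(expected), abs=1e-12)


class TestNodalEfficiency:
    def test_worked_examples(self, triangle, path3):
        assert nodal_efficiency(triangle) == pytest.approx([1, 1, 1])
        assert nodal_efficiency(path3) == pytest.approx([0.75, 1.0, 0.75])

    def test_isolated_node_is_zero(self):
        m = matrix_from_edges(3, {(0, 1): 1})
        assert nodal_efficiency(m)[2] == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        w = random_weighted_graph(n, 0.5, rng)
        assert np.allclose(shortest_distances(w), brute_distances(w))
        assert global_efficiency(w) == pytest.approx(brute_global_efficiency(w), abs=1e-12)
        lp, lp_oracle = char_path_length(w), brute_char_path_length(w)
        assert (np.isnan(lp) and np.isnan(lp_oracle)) or lp == pytest.approx(
            lp_oracle, abs=1e-12
        )
        assert nodal_efficiency(w) == pytest.approx(brute_nodal_efficiency(w), abs=1e-12)


class TestScalingLaws:
    def test_uniform_weight_scaling(self, four_node):
        c = 3.7
        scaled = four_node.copy()
        scaled.weights = scaled.weights * c
        assert nodal_strength(scaled) == pytest.approx(nodal_strength(four_node) * c)
        assert global_efficiency(scaled) == pytest.approx(c * global_efficiency(four_node))
        assert char_path_length(scaled) == pytest.approx(char_path_length(four_node) / c)


class TestRewireNull:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_and_weight_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(12, 0.3, rng)
        null = rewire_null(w, swaps_per_edge=10, rng=seed)
        assert np.array_equal(
            np.sort((null > 0).sum(axis=1)), np.sort((w > 0).sum(axis=1))
        )
        assert np.allclose(
            np.sort(null[np.triu_indices(12, 1)]), np.sort(w[np.triu_indices(12, 1)])
        )
        assert np.array_equal(null, null.T)
        assert np.all(np.diag(null) == 0)

    def test_rewiring_changes_dense_topology(self):
        rng = np.random.default_rng(1)
        w = random_weighted_graph(15, 0.4, rng)
        null = rewire_null(w, swaps_per_edge=10, rng=2)
        assert not np.array_equal(null > 0, w > 0)

    def test_triangle_cannot_be_rewired(self, triangle):
        null = rewire_null(triangle.weights, swaps_per_edge=10, rng=0)
        assert np.array_equal(null, triangle.weights)

    def test_too_few_edges_returns_copy(self):
        m = matrix_from_edges(3, {(0, 1): 2})
        assert np.array_equal(rewire_null(m.weights, rng=0), m.weights)


class TestSmallWorld:
    def test_triangle_normalizes_to_exactly_one(self, triangle):
        sw = small_world(triangle, NullEnsembleConfig(n_nulls=5, seed=0))
        assert sw.lambda_ == 1.0 and sw.gamma == 1.0 and sw.sigma == 1.0

    def test_sigma_is_gamma_over_lambda(self, small_template):
        sw = small_world(
            small_template.mean_weight, NullEnsembleConfig(n_nulls=10, seed=3)
        )
        assert sw.sigma == sw.gamma / sw.lambda_


class TestGlobalMetricsBundle:
    def test_triangle_bundle(self, triangle):
        gm = global_metrics(triangle, NullEnsembleConfig(n_nulls=5, seed=0))
        assert gm.as_dict() == pytest.approx(
            {"Sp": 2, "Eglob": 1, "Eloc": 1, "Lp": 1, "Cp": 1,
             "lambda": 1, "gamma": 1, "sigma": 1}
        )
        assert gm.connectedness_flag

    def test_recomputation_with_same_seed_is_identical(self, small_template):
        cfg = NullEnsembleConfig(n_nulls=8, seed=11)
        a = global_metrics(small_template.mean_weight, cfg)
        b = global_metrics(small_template.mean_weight, cfg)
        assert a == b

    def test_binarized_equals_weighted_on_unit_weights(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = (random_weighted_graph(8, 0.5, rng) > 0).astype(float)
            m = matrix_from_edges(8, {})
            m.weights = w
            cfg = NullEnsembleConfig(n_nulls=5, seed=1)
            assert global_metrics(m, cfg) == global_metrics(binarize(m), cfg)
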