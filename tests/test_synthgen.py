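import numpy as np
import pytest

from connrel.netbuild import coarsen_network
from connrel.reliability import icc_array
from connrel.synthgen import (
    TRTConfig,
    make_template,
    simulate_endpoints,
    simulate_trt,
    subdivide_template,
)


def _edge_panels(template, dataset):
    iu, ju = np.nonzero(np.triu(template.mean_weight, 1))
    arr = dataset.to_array()[:, :, iu, ju]
    return np.moveaxis(arr, (0, 1), (-2, -1))


class TestMakeTemplate:
    def test_default_emulation_scale(self):
        t = make_template(80, target_density=0.2, core_fraction=0.15, weight_scale=50, seed=1)
        assert 0.16 <= t.density <= 0.24
        s = t.mean_weight.sum(axis=1)
        assert s[t.core_flag].mean() > s[~t.core_flag].mean()
        assert np.allclose(t.mean_weight, np.round(t.mean_weight))

    def test_density_one_gives_complete_graph(self):
        t = make_template(4, target_density=1.0, core_fraction=0.3, seed=2)
        off = ~np.eye(4, dtype=bool)
        assert np.all(t.mean_weight[off] > 0)

    def test_deterministic_given_seed(self):
        a = make_template(30, seed=9)
        b = make_template(30, seed=9)
        assert np.array_equal(a.mean_weight, b.mean_weight)
        assert a.node_class == b.node_class
        c = make_template(30, seed=10)
        assert not np.array_equal(a.mean_weight, c.mean_weight)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            make_template(3)
        with pytest.raises(ValueError):
            make_template(10, target_density=0.0)
        with pytest.raises(ValueError):
            make_template(10, core_fraction=1.5)


class TestSubdivide:
    def test_factor_below_two_rejected(self, small_template):
        with pytest.raises(ValueError):
            subdivide_template(small_template, 1)

    def test_two_node_single_edge_conservation(self):
        t = make_template(4, target_density=1.0, core_fraction=0.3, seed=3)
        hi, node_map = subdivide_template(t, 2, seed=4)
        assert hi.n_nodes == 8
        # every low pair's weight is preserved across its 4 high pairs
        for i in range(4):
            for j in range(4):
                block = hi.mean_weight[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                assert block.sum() == t.mean_weight[i, j]
        assert set(node_map.values()) == set(t.node_labels)

    def test_coarsen_inverts_subdivision_exactly(self, small_template):
        hi, node_map = subdivide_template(small_template, 3, seed=5)
        low = coarsen_network(hi.as_matrix("high"), node_map)
        assert low.node_labels == small_template.node_labels
        assert np.array_equal(low.weights, small_template.mean_weight)

    def test_classes_and_core_inherited(self, small_template):
        hi, node_map = subdivide_template(small_template, 2, seed=6)
        for h, low in node_map.items():
            assert hi.node_class[h] == small_template.node_class[low]


class TestSimulateTRT:
    def test_no_within_noise_means_identical_sessions(self, small_template):
        cfg = TRTConfig(n_subjects=4, sigma_bs2=0.1, sigma_ws2=0.0, seed=1)
        ds = simulate_trt(small_template, cfg)
        for row in ds.matrices:
            assert np.array_equal(row[0].weights, row[1].weights)

    def test_no_noise_reproduces_template(self, small_template):
        cfg = TRTConfig(n_subjects=3, sigma_bs2=0.0, sigma_ws2=0.0, seed=1)
        ds = simulate_trt(small_template, cfg)
        for row in ds.matrices:
            for m in row:
                assert np.array_equal(m.weights, small_template.mean_weight)

    def test_deterministic_and_absent_edges_stay_zero(self, small_template):
        cfg = TRTConfig(n_subjects=3, sigma_bs2=0.2, sigma_ws2=0.2, seed=5)
        a = simulate_trt(small_template, cfg).to_array()
        b = simulate_trt(small_template, cfg).to_array()
        assert np.array_equal(a, b)
        absent = small_template.mean_weight == 0
        assert np.all(a[:, :, absent] == 0)

    def test_dropout_zeroes_present_edges(self, small_template):
        cfg = TRTConfig(n_subjects=5, sigma_bs2=0.0, sigma_ws2=0.0, dropout_prob=0.3, seed=2)
        arr = simulate_trt(small_template, cfg).to_array()
        present = small_template.mean_weight > 0
        vals = arr[:, :, present]
        assert (vals == 0).any()
        assert (vals > 0).any()

    def test_lognormal_counts_are_positive_integers(self, small_template):
        cfg = TRTConfig(
            n_subjects=3, sigma_bs2=0.05, sigma_ws2=0.05,
            noise_model="lognormal_count", seed=3,
        )
        arr = simulate_trt(small_template, cfg).to_array()
        present = small_template.mean_weight > 0
        vals = arr[:, :, present]
        assert np.allclose(vals, np.round(vals))
        assert np.all(vals >= 1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TRTConfig(n_subjects=3, n_sessions=1)
        with pytest.raises(ValueError):
            TRTConfig(n_subjects=3, sigma_bs2=-1)
        with pytest.raises(ValueError):
            TRTConfig(n_subjects=3, dropout_prob=1.0)
        with pytest.raises(ValueError):
            TRTConfig(n_subjects=3, noise_model="poisson")


class TestVarianceStructure:
    def test_absolute_mode_recovers_components(self):
        """Sample between/within variances match sigma_bs2 + sigma_ws2/m and
        sigma_ws2 within 3 standard errors at n = 500."""
        t = make_template(10, target_density=0.5, core_fraction=0.2, seed=8)
        sbs2, sws2, n, m = 3.0, 1.0, 500, 2
        cfg = TRTConfig(
            n_subjects=n, sigma_bs2=sbs2, sigma_ws2=sws2,
            variance_mode="absolute", seed=13,
        )
        ds = simulate_trt(t, cfg)
        iu, ju = np.nonzero(np.triu(t.mean_weight, 1))
        vals = ds.to_array()[:, :, iu, ju]  # (n, m, E)
        n_edges = len(iu)

        subj_means = vals.mean(axis=1)  # (n, E)
        var_between = subj_means.var(axis=0, ddof=1).mean()
        expect_between = sbs2 + sws2 / m
        # SE of a sample variance ~ expect * sqrt(2/(n-1)); edges are
        # independent so the mean over E edges shrinks it by sqrt(E)
        se_between = expect_between * np.sqrt(2 / (n - 1)) / np.sqrt(n_edges)
        assert abs(var_between - expect_between) < 3 * se_between

        var_within = ((vals - subj_means[:, None, :]) ** 2).sum(axis=(0, 1)) / (
            n * (m - 1)
        )
        se_within = sws2 * np.sqrt(2 / (n * (m - 1))) / np.sqrt(n_edges)
        assert abs(var_within.mean() - sws2) < 3 * se_within

    def test_more_session_noise_never_raises_mean_icc(self, small_template):
        """Monotonicity over a seed grid: mean edge ICC is non-increasing in
        the within-subject variance."""
        means = []
        for sws2 in (0.5, 1.0, 2.0, 4.0):
            per_seed = []
            for seed in range(4):
                cfg = TRTConfig(
                    n_subjects=40, sigma_bs2=1.0, sigma_ws2=sws2,
                    variance_mode="absolute", seed=seed,
                )
                ds = simulate_trt(small_template, cfg)
                iccs, _, _, _ = icc_array(_edge_panels(small_template, ds))
                per_seed.append(iccs.mean())
            means.append(np.mean(per_seed))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestSimulateEndpoints:
    def test_emits_exact_multiset(self, four_node):
        table = simulate_endpoints(four_node, seed=1)
        assert len(table) == 10  # 3 + 3 + 3 + 1 streamlines
        assert sorted(tuple(sorted(r)) for r in table.records).count(("A", "B")) == 3

    def test_empty_matrix_gives_empty_table(self):
        from conftest import matrix_from_edges

        assert len(simulate_endpoints(matrix_from_edges(3, {}), seed=0)) == 0

    def test_non_integer_weights_rejected(self):
        from conftest import matrix_from_edges

        m = matrix_from_edges(2, {(0, 1): 1.5})
        with pytest.raises(ValueError, match="round"):
            simulate_endpoints(m, seed=0)
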