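"""Cluster-permutation engines, Spearman maps, bootstrap CI, circular stats.

Independent oracles: scipy.stats.spearmanr for rank correlations, pingouin's
circular routines for the Rayleigh test, scipy.stats.circmean for the mean
direction.
"""

import numpy as np
import pytest
from scipy.stats import circmean, spearmanr

from prestim.cluster import (
    Cluster,
    ClusterConfig,
    SpatioTemporalGraph,
    _signed_min_abs,
    bootstrap_ci,
    circular_mean,
    cluster_permutation_correlation,
    cluster_permutation_pos,
    clusters_from_map,
    conjunction_test,
    rayleigh_test,
    spearman_map,
)
from prestim.synth import grid_layout


@pytest.fixture(scope="module")
def lay():
    return grid_layout(4, 4)


@pytest.fixture(scope="module")
def graph(lay):
    return SpatioTemporalGraph(lay.adjacency, 20)


class TestSpearmanMap:
    def test_monotone_and_reversed(self):
        n = 8
        beh = np.arange(n, dtype=float)
        maps = np.tile(beh[:, None, None], (1, 2, 3))
        res = spearman_map(maps, beh)
        np.testing.assert_allclose(res.r, 1.0)
        res = spearman_map(maps, beh[::-1].copy())
        np.testing.assert_allclose(res.r, -1.0)

    def test_tie_handling_matches_scipy(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 4.0])
        y = np.array([0.3, 0.1, 0.5, 0.2, 0.9, 0.9])
        res = spearman_map(x[:, None, None], y)
        assert res.r[0, 0] == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_t_transform(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 1, 1))
        y = rng.standard_normal(10)
        res = spearman_map(x, y)
        r = res.r[0, 0]
        assert res.t[0, 0] == pytest.approx(r * np.sqrt(8 / (1 - r**2)))

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman_map(np.zeros((8, 1, 1)), np.ones(8))  # constant behavior
        with pytest.raises(ValueError):
            spearman_map(np.zeros((3, 1, 1)), np.arange(3.0))  # too few subjects


class TestClustersFromMap:
    def test_no_suprathreshold_points(self, graph):
        assert clusters_from_map(np.zeros((16, 20)), -1.0, 1.0, graph) == []

    def test_single_sensor_temporal_run(self, graph):
        m = np.zeros((16, 20))
        m[5, 4:16] = 2.0  # 12 consecutive samples
        (cl,) = clusters_from_map(m, -1.0, 1.0, graph, min_cluster_size=10)
        assert cl.stat == pytest.approx(24.0)
        assert len(cl.points) == 12
        assert set(cl.members(20)[:, 0]) == {5}

    def test_min_cluster_size_drops_small(self, graph):
        m = np.zeros((16, 20))
        m[5, 4:13] = 2.0  # 9 points < 10
        assert clusters_from_map(m, -1.0, 1.0, graph, min_cluster_size=10) == []

    def test_signs_cluster_separately(self, graph):
        m = np.zeros((16, 20))
        m[2, 0:12] = 3.0
        m[9, 5:17] = -3.0
        cl = clusters_from_map(m, -1.0, 1.0, graph, min_cluster_size=10)
        assert sorted(c.sign for c in cl) == [-1, 1]

    def test_min_neighbors_removes_isolated_points(self, graph):
        m = np.zeros((16, 20))
        m[5, 10] = 2.0  # isolated: no suprathreshold spatial neighbor
        assert clusters_from_map(m, -1.0, 1.0, graph, min_neighbors=2) == []
        # a 3x3 spatial patch at one time point survives min_neighbors=2
        for s in (1, 2, 3, 5, 6, 7, 9, 10, 11):
            m[s, 10] = 2.0
        cl = clusters_from_map(m, -1.0, 1.0, graph, min_neighbors=2)
        assert len(cl) == 1

    def test_spatial_adjacency_merges_sensors(self, graph):
        m = np.zeros((16, 20))
        m[5, 3:8] = 1.5
        m[6, 3:8] = 1.5  # sensors 5,6 are rook-adjacent in a 4x4 grid
        (cl,) = clusters_from_map(m, -1.0, 1.0, graph)
        assert len(cl.points) == 10


class TestPOSClusterTest:
    def test_rank_property_observed_is_null_draw(self, lay):
        rng = np.random.default_rng(1)
        null = rng.standard_normal((200, 16, 20)).astype(np.float32)
        res = cluster_permutation_pos(
            null[0].astype(float), null[1:], lay.adjacency,
            ClusterConfig(min_cluster_size=1),
        )
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0

    def test_detects_injected_opposition_block(self, lay, graph):
        rng = np.random.default_rng(2)
        null = rng.standard_normal((400, 16, 20)).astype(np.float32) * 0.1
        obs = 0.1 * rng.standard_normal((16, 20))
        obs[5:7, :] += 1.5  # strong POS on two adjacent sensors, all times
        res = cluster_permutation_pos(
            obs, null, lay.adjacency,
            ClusterConfig(min_cluster_size=10, min_neighbors=0),
            graph=SpatioTemporalGraph(lay.adjacency, 20),
        )
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert sig and {5, 6} <= set(sig[0].members(20)[:, 0])

    def test_too_few_draws_for_percentile_errors(self, lay):
        with pytest.raises(ValueError):
            cluster_permutation_pos(np.zeros((16, 20)), np.zeros((10, 16, 20)), lay.adjacency)


class TestCorrelationClusterTest:
    def test_detects_strong_coupling(self, lay):
        rng = np.random.default_rng(3)
        n = 13
        beh = np.linspace(0.1, 0.9, n)
        patch = [5, 6, 9, 10]  # 2x2 block: every member keeps >= 2 spatial neighbors
        maps = rng.standard_normal((n, 16, 20))
        maps[:, patch, :] += 4.0 * beh[:, None, None]
        res = cluster_permutation_correlation(
            maps, beh, lay.adjacency, ClusterConfig(n_permutations=200), seed=0
        )
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert sig
        assert set(patch) & set(np.concatenate([c.members(20)[:, 0] for c in sig]))

    def test_reproducible_given_seed(self, lay):
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((8, 16, 20))
        beh = rng.standard_normal(8)
        cfg = ClusterConfig(n_permutations=150)
        a = cluster_permutation_correlation(maps, beh, lay.adjacency, cfg, seed=9)
        b = cluster_permutation_correlation(maps, beh, lay.adjacency, cfg, seed=9)
        np.testing.assert_array_equal(a.null_max, b.null_max)

    def test_defaults_match_protocol(self):
        cfg = ClusterConfig()
        assert cfg.forming_alpha == 0.01
        assert cfg.min_neighbors == 2
        assert cfg.n_permutations == 4000

    def test_few_permutations_warns(self, lay):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning):
            cluster_permutation_correlation(
                rng.standard_normal((6, 16, 20)), rng.standard_normal(6), lay.adjacency,
                ClusterConfig(n_permutations=50), seed=0,
            )


class TestConjunction:
    def test_signed_min_abs_identities(self):
        a = np.array([0.5, -0.7, 0.2])
        np.testing.assert_allclose(_signed_min_abs(a, a), a)
        np.testing.assert_allclose(_signed_min_abs(a, np.zeros(3)), np.zeros(3))
        np.testing.assert_allclose(_signed_min_abs(np.array([0.5]), np.array([-0.9])), [0.0])
        np.testing.assert_allclose(_signed_min_abs(np.array([-0.5]), np.array([-0.9])), [-0.5])

    def test_independent_null_maps_rarely_significant(self, lay):
        rng = np.random.default_rng(6)
        n = 13
        hits = 0
        for k in range(10):
            a = rng.standard_normal((n, 16, 20))
            b = rng.standard_normal((n, 16, 20))
            res = conjunction_test(
                a, rng.standard_normal(n), b, rng.standard_normal(n), lay.adjacency,
                ClusterConfig(n_permutations=150, min_neighbors=0, cluster_stat="max"), seed=k,
            )
            hits += bool([c for c in res.clusters if c.p_value < 0.05])
        assert hits <= 2

    def test_geometry_mismatch_errors(self, lay):
        with pytest.raises(ValueError):
            conjunction_test(
                np.zeros((6, 16, 20)), np.arange(6.0), np.zeros((6, 16, 21)), np.arange(6.0),
                lay.adjacency,
            )


class TestBootstrapCI:
    def test_identical_vectors_give_degenerate_interval(self):
        x = np.arange(13.0)
        lo, hi, r, _ = bootstrap_ci(x, x, n_boot=200, seed=0)
        assert (lo, hi, r) == (1.0, 1.0, 1.0)

    def test_defaults(self):
        import inspect

        sig = inspect.signature(bootstrap_ci)
        assert sig.parameters["n_boot"].default == 2000
        assert sig.parameters["level"].default == 0.95

    def test_interval_brackets_observed_on_noisy_data(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(13)
        y = 0.8 * x + 0.6 * rng.standard_normal(13)
        lo, hi, r, skipped = bootstrap_ci(x, y, n_boot=500, seed=1)
        assert lo <= r <= hi
        assert skipped == 0

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.arange(3.0), np.arange(3.0))


class TestCircular:
    def test_rayleigh_uniform_cases(self):
        evenly = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        z, p = rayleigh_test(evenly)
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
        z, p = rayleigh_test([0.0, np.pi])
        assert p == pytest.approx(1.0)

    def test_rayleigh_concentrated(self):
        z, p = rayleigh_test(np.full(13, 0.7))
        assert z == pytest.approx(13.0)
        assert p < 1e-4

    def test_rayleigh_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        ang = rng.vonmises(1.0, 1.5, size=40)
        z, p = rayleigh_test(ang)
        z_ref, p_ref = pingouin.circ_rayleigh(ang)
        assert z == pytest.approx(z_ref, rel=1e-6)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_rayleigh_empty_errors(self):
        with pytest.raises(ValueError):
            rayleigh_test([])

    @pytest.mark.parametrize(
        "angles,expected_deg",
        [([30.0, 30.0, 30.0], 30.0), ([-45.0, 45.0], 0.0), ([170.0, -170.0], 180.0)],
    )
    def test_circular_mean_cases(self, angles, expected_deg):
        rad = np.deg2rad(angles)
        assert np.rad2deg(circular_mean(rad)) == pytest.approx(expected_deg, abs=1e-9)

    def test_circular_mean_matches_scipy(self):
        rng = np.random.default_rng(9)
        ang = rng.vonmises(-2.0, 2.0, size=25)
        ours = circular_mean(ang)
        ref = circmean(ang, high=np.pi, low=-np.pi)
        assert np.angle(np.exp(1j * (ours - ref))) == pytest.approx(0.0, abs=1e-9)

    def test_zero_resultant_errors(self):
        with pytest.raises(ValueError):
            circular_mean([0.0, np.pi])
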