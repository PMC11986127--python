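import itertools

import numpy as np
import pytest

import mstates as ms
from mstates.cluster import ClusterParams, _center_normalize, _principal_map


def brute_force_best_gev(topos, gfp, k):
    """Exhaustive oracle: every k-partition -> principal-map centroids ->
    winner-takes-all GEV; returns the maximum over partitions."""
    n = len(topos)
    best = 0.0
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        if len(set(assign)) < k:
            continue
        xn = _center_normalize(topos)
        maps = np.array([_principal_map(xn[assign == c], gfp[assign == c])
                         for c in range(k)])
        gev = ms.gev_of_solution(
            topos, gfp, np.argmax(np.abs(xn @ maps.T), axis=1), maps)
        best = max(best, gev)
    return best


def _random_topos(rng, n, n_ch=6):
    x = rng.standard_normal((n, n_ch))
    return x - x.mean(axis=1, keepdims=True)


class TestSpatialCorrelation:
    def test_polarity_flip_is_identical(self):
        m = np.array([1.0, -2.0, 1.0, 0.0])
        assert ms.spatial_correlation(m, -m) == pytest.approx(1.0)
        assert ms.spatial_correlation(m, -m, ignore_polarity=False) == pytest.approx(-1.0)

    def test_self_correlation_is_one(self):
        m = np.array([0.3, -0.1, 0.5, -0.7])
        assert ms.spatial_correlation(m, m) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert ms.spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.spatial_correlation(np.zeros(4), np.ones(4))


class TestGev:
    def test_worked_arithmetic(self):
        # two samples, GFP (1,2), corr (1, 0.5) -> (1 + 1)/(1 + 4) = 0.4
        maps = np.array([[1.0, -1.0, 0.0, 0.0]])
        x0 = maps[0]
        # construct a frame with |corr| = 0.5 to the map
        orth = np.array([0.0, 0.0, 1.0, -1.0])
        x1 = 0.5 * x0 / np.linalg.norm(x0) + np.sqrt(0.75) * orth / np.linalg.norm(orth)
        gev = ms.gev_of_solution(np.vstack([x0, x1]), np.array([1.0, 2.0]),
                                 np.array([0, 0]), maps)
        assert gev == pytest.approx(0.4, abs=1e-12)

    def test_perfect_fit_is_one(self):
        maps = _random_topos(np.random.default_rng(0), 2)
        topos = np.vstack([maps[0] * 2.0, maps[1] * 0.5, -maps[0]])
        gev = ms.gev_of_solution(topos, topos.std(axis=1),
                                 np.array([0, 1, 0]), maps)
        assert gev == pytest.approx(1.0)

    def test_all_unassigned_is_zero(self):
        topos = _random_topos(np.random.default_rng(1), 3)
        gev = ms.gev_of_solution(topos, np.ones(3),
                                 np.full(3, ms.UNASSIGNED), topos[:1])
        assert gev == 0.0


class TestModifiedKmeans:
    def test_noiseless_duplicates_reach_gev_one(self):
        rng = np.random.default_rng(2)
        base = _random_topos(rng, 3, 8)
        topos = np.repeat(base, 4, axis=0) * rng.uniform(0.5, 2, 12)[:, None]
        topos[::2] *= -1  # polarity flips must not matter
        sol = ms.modified_kmeans(topos, 3, ClusterParams(n_restarts=20, seed=0,
                                                         min_assign_corr=0.0))
        assert sol.gev == pytest.approx(1.0, abs=1e-9)
        for b in _center_normalize(base):
            assert max(abs(float(b @ m)) for m in
                       _center_normalize(sol.maps.maps)) == pytest.approx(1.0, abs=1e-6)

    def test_k1_equals_leading_eigenvector_share(self):
        rng = np.random.default_rng(3)
        topos = _random_topos(rng, 30, 10)
        g = topos.std(axis=1)
        sol = ms.modified_kmeans(topos, 1, ClusterParams(n_restarts=3, seed=1,
                                                         min_assign_corr=0.0))
        xn = _center_normalize(topos)
        s = (xn * g[:, None]).T @ (xn * g[:, None])
        vals = np.linalg.eigvalsh(s)
        assert sol.gev == pytest.approx(vals[-1] / np.sum(g ** 2), abs=1e-9)

    def test_matches_brute_force_on_8_points_k2(self):
        rng = np.random.default_rng(4)
        topos = _random_topos(rng, 8, 5)
        g = topos.std(axis=1)
        sol = ms.modified_kmeans(topos, 2, ClusterParams(n_restarts=40, seed=2,
                                                         min_assign_corr=0.0))
        assert sol.gev == pytest.approx(brute_force_best_gev(topos, g, 2), abs=1e-9)

    def test_k_larger_than_data_rejected(self):
        with pytest.raises(ValueError):
            ms.modified_kmeans(_random_topos(np.random.default_rng(0), 3), 4)

    def test_deterministic_under_seed(self):
        topos = _random_topos(np.random.default_rng(5), 20, 8)
        a = ms.modified_kmeans(topos, 3, ClusterParams(n_restarts=10, seed=7))
        b = ms.modified_kmeans(topos, 3, ClusterParams(n_restarts=10, seed=7))
        np.testing.assert_array_equal(a.maps.maps, b.maps.maps)
        assert a.gev == b.gev

    def test_gev_nondecreasing_in_k(self):
        topos = _random_topos(np.random.default_rng(6), 40, 8)
        gevs = [ms.modified_kmeans(topos, k, ClusterParams(n_restarts=20, seed=3,
                                                           min_assign_corr=0.0)).gev
                for k in (1, 2, 3, 4)]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))

    def test_polarity_invariance_of_solution(self):
        rng = np.random.default_rng(7)
        topos = _random_topos(rng, 15, 6)
        flip = topos.copy()
        flip[::3] *= -1
        a = ms.modified_kmeans(topos, 2, ClusterParams(n_restarts=10, seed=4))
        b = ms.modified_kmeans(flip, 2, ClusterParams(n_restarts=10, seed=4))
        assert a.gev == pytest.approx(b.gev, abs=1e-12)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestSelectOptimalK:
    def test_single_candidate_returned(self):
        topos = _random_topos(np.random.default_rng(0), 10, 5)
        sol = ms.modified_kmeans(topos, 1, ClusterParams(n_restarts=2, seed=0))
        k, diag = ms.select_optimal_k({1: sol}, topos)
        assert k == 1

    def test_planted_k4_chosen(self, montage24, templates4):
        spec = ms.SimulationSpec(n_channels=24, duration_s=40.0, snr=10.0)
        rng = np.random.default_rng(9)
        seq = ms.simulate_state_sequence(spec, rng)
        rec = ms.simulate_eeg(templates4, seq, spec, montage24, rng)
        sol = ms.subject_segmentation(
            rec, ClusterParams(k_range=tuple(range(2, 8)), n_restarts=15, seed=0))
        assert sol.k == 4

    def test_noise_input_reports_all_votes(self):
        topos = _random_topos(np.random.default_rng(1), 60, 10)
        params = ClusterParams(n_restarts=5, seed=1, min_assign_corr=0.0)
        sols = {k: ms.modified_kmeans(topos, k, params) for k in range(2, 7)}
        k, diag = ms.select_optimal_k(sols, topos)
        assert set(diag["votes"]) == {"krzanowski_lai", "elbow", "cross_validation"}
        assert k in sols


class TestGroupClustering:
    def test_consensus_of_identical_subjects(self, templates4):
        sols = []
        for i in range(3):
            mapset = ms.MicrostateMapSet(maps=templates4.maps,
                                         channel_names=templates4.channel_names)
            sols.append(ms.ClusterSolution(maps=mapset,
                                           assignment=np.zeros(4, dtype=int),
                                           gev=1.0))
        params = ClusterParams(k_range=tuple(range(2, 7)), n_restarts=20, seed=0)
        gm = ms.group_clustering(sols, params)
        assert gm.n_maps == 4
        assert gm.level == "group"
        for t in templates4.maps:
            assert max(ms.spatial_correlation(t, g) for g in gm.maps) \
                == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_channel_sets_rejected(self, templates4):
        a = ms.ClusterSolution(
            maps=ms.MicrostateMapSet(maps=templates4.maps,
                                     channel_names=templates4.channel_names),
            assignment=np.zeros(1, dtype=int), gev=0.5)
        other = ms.MicrostateMapSet(maps=templates4.maps,
                                    channel_names=[f"x{i}" for i in range(24)])
        b = ms.ClusterSolution(maps=other, assignment=np.zeros(1, dtype=int), gev=0.5)
        with pytest.raises(ms.ChannelMismatchError):
            ms.group_clustering([a, b])

    def test_needs_two_subjects(self, templates4):
        sol = ms.ClusterSolution(
            maps=templates4, assignment=np.zeros(1, dtype=int), gev=0.5)
        with pytest.raises(ValueError):
            ms.group_clustering([sol])
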