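"""Unit and property tests for the KNN-improved density-peak clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnipose import knn_dpc
from somnipose.knn_dpc import (
    DPCParams,
    DegenerateDataError,
    NoCandidateError,
)
from somnipose.cluster_eval import ari

import _oracles


def three_blobs(seed=0, n_per=50, spread=0.3):
    rng = np.random.default_rng(seed)
    locs = [(0, 0), (5, 5), (10, 0)]
    X = np.concatenate([rng.normal(l, spread, size=(n_per, 2)) for l in locs])
    return X, np.repeat(np.arange(3), n_per)


class TestPairwiseDistances:
    def test_pythagorean_pair(self):
        D, sigma = knn_dpc.pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert sigma == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        D, _ = knn_dpc.pairwise_distances(X)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_matches_double_loop(self):
        X = np.random.default_rng(2).normal(size=(10, 2))
        D, sigma = knn_dpc.pairwise_distances(X)
        B = np.array(_oracles.brute_distance_matrix(X.tolist()))
        assert np.allclose(D, B, rtol=1e-12, atol=1e-12)
        assert sigma == pytest.approx(B.max())

    def test_identical_points_flag_degenerate(self):
        D, sigma = knn_dpc.pairwise_distances(np.zeros((4, 2)))
        assert sigma == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            knn_dpc.pairwise_distances(np.array([[0.0, np.nan], [1.0, 2.0]]))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="two points"):
            knn_dpc.pairwise_distances(np.array([[1.0, 2.0]]))


class TestLocalDensity:
    def test_degenerate_data_raises(self):
        D, sigma = knn_dpc.pairwise_distances(np.zeros((5, 2)))
        with pytest.raises(DegenerateDataError):
            knn_dpc.local_density(D, sigma, DPCParams(k=2))

    def test_k_too_large_raises(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        D, sigma = knn_dpc.pairwise_distances(X)
        with pytest.raises(ValueError, match="k=8"):
            knn_dpc.local_density(D, sigma, DPCParams(k=8))

    def test_all_neighbors_at_diameter_gives_zero(self):
        # point 0 at origin; its 2 neighbors both at the max distance 1
        X = np.array([[0.0], [1.0], [1.0]])
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma, DPCParams(k=2))
        assert rho[0] == pytest.approx(0.0)
        # points 1, 2 see one coincident neighbor and one at sigma
        assert rho[1] == rho[2] == pytest.approx(0.5)

    def test_coincident_neighbors_give_one(self):
        X = np.array([[0.0], [0.0], [0.0], [5.0]])
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma, DPCParams(k=2))
        assert rho[0] == rho[1] == rho[2] == pytest.approx(1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 25), st.integers(1, 4))
    def test_rho_in_unit_interval(self, seed, n, d):
        X = np.random.default_rng(seed).normal(size=(n, d))
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma, DPCParams(k=min(4, n - 1)))
        assert np.all(rho >= 0.0) and np.all(rho <= 1.0)


class TestRepulsionFactor:
    def test_two_points(self):
        X = np.array([[0.0], [3.0]])
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma, DPCParams(k=1))
        delta = knn_dpc.repulsion_factor(D, rho, DPCParams(k=1))
        # both points tie at max density, so both take the max-distance branch
        assert delta[0] == delta[1] == pytest.approx(3.0)

    def test_global_peak_gets_max_distance(self):
        X, _ = three_blobs(seed=3)
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma)
        delta = knn_dpc.repulsion_factor(D, rho)
        peak = int(np.argmax(rho))
        assert delta[peak] == pytest.approx(D[peak].max())

    def test_matches_pair_enumeration(self):
        X = np.random.default_rng(4).normal(size=(12, 2))
        ref = _oracles.brute_dpc(X.tolist(), k=3)
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma, DPCParams(k=3))
        delta = knn_dpc.repulsion_factor(D, rho, DPCParams(k=3))
        assert np.allclose(rho, ref["rho"], rtol=1e-12)
        assert np.allclose(delta, ref["delta"], rtol=1e-12)

    def test_nonnegative(self):
        X = np.random.default_rng(5).normal(size=(30, 2))
        D, sigma = knn_dpc.pairwise_distances(X)
        rho = knn_dpc.local_density(D, sigma)
        assert np.all(knn_dpc.repulsion_factor(D, rho) >= 0.0)


class TestCentrality:
    def test_direct_evaluation(self):
        g = knn_dpc.centrality(np.array([0.5]), np.array([0.4]), DPCParams(m=2))
        assert g[0] == pytest.approx(0.04)

    def test_exponent_one_is_product(self):
        rho = np.array([0.2, 0.9])
        delta = np.array([1.5, 0.1])
        g = knn_dpc.centrality(rho, delta, DPCParams(m=1))
        assert np.allclose(g, rho * delta)

    def test_zero_density_annihilates(self):
        g = knn_dpc.centrality(np.array([0.0, 0.5]), np.array([9.0, 1.0]))
        assert g[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            knn_dpc.centrality(np.array([-0.1]), np.array([1.0]))


class TestSelectCenters:
    def test_geometric_sequence_single_cluster(self):
        # gaps (0.5, 0.25, 0.125), mean ~0.2917: only the first exceeds it
        rho = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        delta = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        gamma = np.array([1.0, 0.5, 0.25, 0.125, 0.0, 0.0])
        centers, K = knn_dpc.select_centers(rho, delta, gamma)
        assert K == 1
        assert centers.tolist() == [0]

    def test_boundary_gap_keeps_center_group(self):
        # three strong centers then a collapse: the boundary gap is g3
        rho = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        delta = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        gamma = np.array([10.0, 9.5, 9.0, 0.2, 0.1, 0.0])
        centers, K = knn_dpc.select_centers(rho, delta, gamma)
        assert K == 3
        assert centers.tolist() == [0, 1, 2]

    def test_single_candidate(self):
        rho = np.array([0.9, 0.1, 0.1])
        delta = np.array([2.0, 0.1, 0.1])
        gamma = knn_dpc.centrality(rho, delta)
        centers, K = knn_dpc.select_centers(rho, delta, gamma)
        assert K == 1 and centers.tolist() == [0]

    def test_no_candidates_raises(self):
        rho = np.array([0.5, 0.5])
        delta = np.array([1.0, 1.0])
        with pytest.raises(NoCandidateError):
            knn_dpc.select_centers(rho, delta, rho * delta)

    def test_equal_gaps_fall_back_to_all_candidates(self):
        rho = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
        delta = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
        gamma = np.array([3.0, 2.0, 1.0, 0.0, 0.0])  # strict > never fires
        with pytest.warns(UserWarning, match="no centrality gap"):
            centers, K = knn_dpc.select_centers(rho, delta, gamma)
        assert K == 3

    def test_single_blob_estimates_one_cluster(self):
        X = np.random.default_rng(6).normal(size=(80, 2))
        res = knn_dpc.fit(X)
        assert res.n_clusters == 1


class TestAssignLabels:
    def test_all_points_centers(self):
        X = np.random.default_rng(7).normal(size=(4, 2))
        D, _ = knn_dpc.pairwise_distances(X)
        rho = np.array([0.4, 0.3, 0.2, 0.1])
        labels = knn_dpc.assign_labels(D, rho, np.arange(4))
        assert sorted(labels.tolist()) == [0, 1, 2, 3]

    def test_chain_inheritance(self):
        # a-b-c with decreasing density, a the only center: everything is 0
        D, _ = knn_dpc.pairwise_distances(np.array([[0.0], [1.0], [2.1]]))
        labels = knn_dpc.assign_labels(D, np.array([0.9, 0.5, 0.1]), np.array([0]))
        assert labels.tolist() == [0, 0, 0]

    def test_two_blob_membership(self):
        rng = np.random.default_rng(8)
        X = np.concatenate(
            [rng.normal(0, 0.2, size=(40, 2)), rng.normal(6, 0.2, size=(40, 2))]
        )
        res = knn_dpc.fit(X)
        truth = np.repeat([0, 1], 40)
        assert res.n_clusters == 2
        assert ari(truth, res.labels) == pytest.approx(1.0)

    def test_empty_centers_rejected(self):
        D, _ = knn_dpc.pairwise_distances(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError, match="non-empty"):
            knn_dpc.assign_labels(D, np.array([0.1, 0.2]), np.array([], dtype=int))


class TestFit:
    def test_three_blob_recovery(self):
        X, truth = three_blobs(seed=0, n_per=50)
        res = knn_dpc.fit(X)
        assert res.n_clusters == 3
        assert ari(truth, res.labels) >= 0.9

    def test_deterministic(self):
        X, _ = three_blobs(seed=1)
        r1, r2 = knn_dpc.fit(X), knn_dpc.fit(X)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centers, r2.centers)

    def test_permutation_equivariance(self):
        X, _ = three_blobs(seed=2)
        perm = np.random.default_rng(9).permutation(len(X))
        r1 = knn_dpc.fit(X)
        r2 = knn_dpc.fit(X[perm])
        assert r1.n_clusters == r2.n_clusters
        assert ari(r1.labels[perm], r2.labels) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        X, _ = three_blobs(seed=3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = X @ R.T + np.array([13.0, -4.0])
        r1, r2 = knn_dpc.fit(X), knn_dpc.fit(Y)
        assert r1.n_clusters == r2.n_clusters
        assert np.array_equal(r1.labels, r2.labels)
        assert np.allclose(r1.profile.rho, r2.profile.rho, atol=1e-9)
        assert np.allclose(r1.profile.delta, r2.profile.delta, atol=1e-9)

    def test_uniform_scaling(self):
        X, _ = three_blobs(seed=4)
        c = 7.3
        r1, r2 = knn_dpc.fit(X), knn_dpc.fit(c * X)
        assert np.allclose(r1.profile.rho, r2.profile.rho, atol=1e-12)
        assert np.allclose(c * r1.profile.delta, r2.profile.delta, rtol=1e-9)
        assert r1.n_clusters == r2.n_clusters
        assert np.array_equal(r1.labels, r2.labels)

    def test_posture_feature_set_recovers_six_classes(self):
        from somnipose import synthetic_data

        ds = synthetic_data.generate_dataset(
            synthetic_data.GeneratorConfig(n_subjects=15, sets_per_posture=10, seed=42)
        )
        res = knn_dpc.fit(synthetic_data.channel_means(ds))
        assert res.n_clusters == 6
        assert ari(ds.labels, res.labels) >= 0.95


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_pipeline_matches_nested_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        d = int(rng.integers(1, 4))
        k = int(rng.integers(2, min(8, n - 1) + 1))
        X = rng.normal(size=(n, d)) * rng.uniform(0.5, 3.0)
        ref = _oracles.brute_dpc(X.tolist(), k=k)
        params = DPCParams(k=k)
        if ref["K"] == 0:
            with pytest.raises(NoCandidateError):
                knn_dpc.fit(X, params)
            return
        res = knn_dpc.fit(X, params)
        assert np.allclose(res.profile.rho, ref["rho"], rtol=1e-12)
        assert np.allclose(res.profile.delta, ref["delta"], rtol=1e-12)
        assert np.allclose(res.profile.gamma, ref["gamma"], rtol=1e-12)
        assert res.n_clusters == ref["K"]
        assert res.centers.tolist() == ref["centers"]
        assert res.labels.tolist() == ref["labels"]


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        X = np.random.default_rng(10).normal(size=(12, 3))
        truth = np.repeat([0, 1], 6)
        df = pd.DataFrame(X, columns=["f0", "f1", "f2"])
        df["label"] = truth
        path = tmp_path / "features.csv"
        df.to_csv(path, index=False)
        X2, y2 = knn_dpc.read_features(path)
        assert np.allclose(X, X2)
        assert np.array_equal(truth, y2)

    def test_hdf5_read_and_result_output(self, tmp_path):
        import h5py
        import json

        X = np.random.default_rng(11).normal(size=(10, 2))
        with h5py.File(tmp_path / "f.h5", "w") as f:
            f.create_dataset("features", data=X)
        X2, y2 = knn_dpc.read_features(tmp_path / "f.h5")
        assert np.allclose(X, X2) and y2 is None

        res = knn_dpc.fit(np.concatenate([X, X + 8.0]))
        knn_dpc.write_result(
            res, tmp_path / "out.csv", tmp_path / "out.json", DPCParams()
        )
        summary = json.loads((tmp_path / "out.json").read_text())
        assert summary["K"] == res.n_clusters
        assert summary["params"] == {"k": 8, "m": 2.0}
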