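"""Supervised Tucker3 clustering: exact recovery, algebraic identities,
and agreement with a brute-force oracle on tiny instances."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from t3brain.feature_tensor import FeatureTensor, matricize
from t3brain.synthetic import TensorSynthSpec, generate_feature_tensor
from t3brain.t3clus import (
    ScoreMatrix,
    TuckerConfig,
    build_indicator,
    component_scores,
    fit,
    kron_loadings,
    loadings,
)

import oracles


def _obs_index(n):
    return [(f"s{i:03d}", c) for i in range(n) for c in ("rest", "meditation")]


class TestIndicator:
    def test_direct_encoding(self):
        U = build_indicator(["rest", "meditation", "rest"], 2)
        assert np.array_equal(U, [[1, 0], [0, 1], [1, 0]])

    def test_gram_is_class_sizes(self):
        U = build_indicator(["rest", "meditation", "rest", "rest"], 2)
        assert np.array_equal(U.T @ U, np.diag([3, 1]))

    def test_wrong_class_count(self):
        with pytest.raises(ValueError):
            build_indicator(["rest", "rest"], 2)
        with pytest.raises(ValueError):
            build_indicator(["a", "b", "c"], 2)


class TestFit:
    def test_noiseless_planted_recovery(self):
        spec = TensorSynthSpec(n_subjects=10, J=30, K=4, delta=1.0, sigma=0.0, seed=3)
        tensor, truth = generate_feature_tensor(spec)
        res = fit(tensor, build_indicator(tensor.labels, 2))
        assert res.loss <= 1e-10
        assert np.max(subspace_angles(res.B, truth.B)) <= 1e-6
        assert np.max(subspace_angles(res.C, truth.C)) <= 1e-6
        top = np.argsort(-np.abs(res.B[:, 0]))[: len(truth.planted_region_set)]
        assert sorted(top) == list(truth.planted_region_set)

    def test_identical_rows_within_class_full_rank_zero_loss(self, rng):
        J, K = 3, 2
        rows = {c: rng.standard_normal(J * K) for c in ("rest", "meditation")}
        obs = _obs_index(4)
        X_mat = np.array([rows[c] for _, c in obs])
        U = build_indicator([c for _, c in obs], 2)
        res = fit(X_mat, U, TuckerConfig(Q=J, R=K), J=J, K=K)
        assert res.loss == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_loadings(self, rng):
        spec = TensorSynthSpec(n_subjects=8, J=12, K=4, delta=1.0, sigma=0.5, seed=9)
        tensor, _ = generate_feature_tensor(spec)
        res = fit(tensor, build_indicator(tensor.labels, 2))
        assert np.allclose(res.B.T @ res.B, np.eye(2), atol=1e-10)
        assert np.allclose(res.C.T @ res.C, np.eye(1), atol=1e-10)

    def test_loss_at_least_within_class_residual(self, rng):
        spec = TensorSynthSpec(n_subjects=8, J=12, K=4, delta=1.0, sigma=0.5, seed=10)
        tensor, _ = generate_feature_tensor(spec)
        U = build_indicator(tensor.labels, 2)
        X = matricize(tensor)
        P = U @ np.linalg.inv(U.T @ U) @ U.T
        irreducible = float(np.sum((X - P @ X) ** 2))
        res = fit(tensor, U)
        assert res.loss >= irreducible - 1e-8

    def test_invariant_to_row_permutation_and_relabeling(self, rng):
        spec = TensorSynthSpec(n_subjects=6, J=10, K=4, delta=1.0, sigma=0.3, seed=4)
        tensor, _ = generate_feature_tensor(spec)
        U = build_indicator(tensor.labels, 2)
        X = matricize(tensor)
        res = fit(X, U, J=10, K=4)
        perm = rng.permutation(X.shape[0])
        res_p = fit(X[perm], U[perm], J=10, K=4)
        assert res_p.loss == pytest.approx(res.loss, rel=1e-10)
        assert np.abs(res_p.B) == pytest.approx(np.abs(res.B), abs=1e-8)
        res_r = fit(X, U[:, ::-1], J=10, K=4)  # class relabeling
        assert res_r.loss == pytest.approx(res.loss, rel=1e-10)
        assert np.abs(res_r.B[:, 0]) == pytest.approx(np.abs(res.B[:, 0]), abs=1e-8)

    def test_reduced_problem_loss_identity(self, rng):
        # loss on full X equals within-class residual + class-mean residual
        spec = TensorSynthSpec(n_subjects=7, J=9, K=4, delta=0.8, sigma=0.6, seed=12)
        tensor, _ = generate_feature_tensor(spec)
        U = build_indicator(tensor.labels, 2)
        X = matricize(tensor)
        res = fit(tensor, U)
        P = U @ np.linalg.inv(U.T @ U) @ U.T
        within = float(np.sum((X - P @ X) ** 2))
        CB = kron_loadings(res)
        between = float(np.sum((P @ X - P @ X @ CB @ CB.T) ** 2))
        assert res.loss == pytest.approx(within + between, rel=1e-10)

    def test_tiny_instances_match_brute_force(self, rng):
        cfg = TuckerConfig(Q=1, R=1)
        for _ in range(10):
            obs = _obs_index(3)
            X = rng.standard_normal((6, 6))  # J=3, K=2
            U = build_indicator([c for _, c in obs], 2)
            res = fit(X, U, cfg, J=3, K=2)
            W_mat = (U.T @ X) / np.sqrt(U.sum(0))[:, None]
            W = W_mat.reshape(2, 2, 3).transpose(0, 2, 1)
            oracle = oracles.tucker_rank1_loss_oracle(W, float(np.sum(X * X)))
            assert res.loss == pytest.approx(oracle, abs=1e-6)


class TestScoresAndLoadings:
    @pytest.fixture
    def fitted(self):
        spec = TensorSynthSpec(n_subjects=9, J=14, K=4, delta=3.0, sigma=0.1, seed=6)
        tensor, truth = generate_feature_tensor(spec)
        U = build_indicator(tensor.labels, 2)
        return tensor, truth, U, fit(tensor, U)

    def test_centroid_scores_constant_within_class(self, fitted):
        tensor, _, U, res = fitted
        sm = component_scores(res, tensor, U)
        lab = np.asarray(tensor.labels)
        for c in ("rest", "meditation"):
            block = sm.centroid_scores[lab == c]
            assert np.allclose(block, block[0])

    def test_class_means_of_raw_equal_centroid(self, fitted):
        tensor, _, U, res = fitted
        sm = component_scores(res, tensor, U)
        lab = np.asarray(tensor.labels)
        for c in ("rest", "meditation"):
            assert np.allclose(sm.raw_scores[lab == c].mean(0), sm.centroid_scores[lab == c][0])

    def test_raw_scores_are_contractions(self, fitted):
        tensor, _, U, res = fitted
        sm = component_scores(res, tensor, U)
        assert np.linalg.norm(sm.raw_scores) <= np.linalg.norm(matricize(tensor)) + 1e-9

    def test_kron_loading_entries(self, fitted):
        _, _, _, res = fitted
        CB = kron_loadings(res)
        J, Q = res.B.shape
        K, R = res.C.shape
        for j in (0, 3, J - 1):
            for k in range(K):
                for q in range(Q):
                    for r in range(R):
                        assert CB[k * J + j, r * Q + q] == pytest.approx(
                            res.C[k, r] * res.B[j, q], abs=1e-12
                        )

    def test_first_component_tables(self, fitted):
        tensor, truth, _, res = fitted
        tabs = loadings(res, tensor.region_names, tensor.metric_names)
        assert np.allclose(np.linalg.norm(res.B, axis=0), 1.0)
        top = tabs["regions"].loading.abs().nlargest(len(truth.planted_region_set)).index
        assert sorted(tabs["regions"].region[t] for t in top) == sorted(
            tensor.region_names[j] for j in truth.planted_region_set
        )
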