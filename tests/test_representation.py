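"""Unit tests for the per-view low-rank representation stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msca.representation import (
    LocalLowRankRepresentation,
    OmicsView,
    SolverConfig,
    affinity_from_representation,
    knn_adjacency,
    l21_shrink,
    solve_lrr,
    svt,
    zscore_features,
    spectral_rescale,
)


def nuclear_objective(J, M, tau):
    return np.linalg.norm(J, "nuc") + np.sum((M - J) ** 2) / (2 * tau)


def l21_objective(E, M, tau):
    return tau * np.linalg.norm(E, axis=0).sum() + 0.5 * np.sum((M - E) ** 2)


class TestKnnAdjacency:
    def test_three_points_on_a_line(self):
        X = np.array([[0.0, 1.0, 10.0]])  # 1 feature, 3 samples
        support = knn_adjacency(X, 1)
        assert support.pairs == {(1, 0), (0, 1), (1, 2)}

    def test_full_support_when_k_is_n_minus_1(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 6))
        support = knn_adjacency(X, 5)
        expected = ~np.eye(6, dtype=bool)
        np.testing.assert_array_equal(support.mask, expected)

    def test_matches_brute_force_distance_ranking(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(5, 20))
        k = 4
        support = knn_adjacency(X, k)
        for j in range(20):
            d = np.linalg.norm(X - X[:, [j]], axis=0)
            d[j] = np.inf
            nearest = set(np.argsort(d, kind="stable")[:k].tolist())
            assert set(np.nonzero(support.mask[:, j])[0].tolist()) == nearest

    def test_ties_broken_by_lower_index(self):
        # three coincident points: each picks the lowest available index
        X = np.zeros((2, 3))
        support = knn_adjacency(X, 1)
        assert support.pairs == {(1, 0), (0, 1), (0, 2)}

    def test_k_too_large_rejected(self):
        X = np.zeros((2, 4))
        with pytest.raises(ValueError, match="k_neighbors"):
            knn_adjacency(X, 4)


class TestProximalOperators:
    def test_svt_zero_matrix(self):
        np.testing.assert_array_equal(svt(np.zeros((3, 3)), 2.0), np.zeros((3, 3)))

    def test_svt_diagonal(self):
        out = svt(np.diag([3.0, 1.0]), 1.0)
        np.testing.assert_allclose(out, np.diag([2.0, 0.0]), atol=1e-12)

    def test_l21_small_column_zeroed(self):
        M = np.array([[0.3], [0.0]])
        np.testing.assert_array_equal(l21_shrink(M, 0.5), np.zeros((2, 1)))

    def test_l21_scaling_factor(self):
        c = np.array([[1.2], [1.6]])  # norm 2
        np.testing.assert_allclose(l21_shrink(c, 0.5), 0.75 * c)

    @pytest.mark.parametrize("seed", range(4))
    def test_svt_minimizes_its_objective(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(4, 4))
        tau = 0.5
        out = svt(M, tau)
        base = nuclear_objective(out, M, tau)
        for _ in range(200):
            pert = out + rng.normal(scale=rng.uniform(1e-4, 0.3), size=out.shape)
            assert base <= nuclear_objective(pert, M, tau) + 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_l21_minimizes_its_objective(self, seed):
        rng = np.random.default_rng(100 + seed)
        M = rng.normal(size=(6, 4))
        tau = 0.8
        out = l21_shrink(M, tau)
        base = l21_objective(out, M, tau)
        for _ in range(200):
            pert = out + rng.normal(scale=rng.uniform(1e-4, 0.3), size=out.shape)
            assert base <= l21_objective(pert, M, tau) + 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 3.0))
    def test_svt_never_increases_singular_values(self, seed, tau):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(5, 5))
        s_in = np.linalg.svd(M, compute_uv=False)
        s_out = np.linalg.svd(svt(M, tau), compute_uv=False)
        assert np.all(s_out <= s_in + 1e-10)
        np.testing.assert_allclose(s_out, np.maximum(s_in - tau, 0.0), atol=1e-8)


def orthogonal_copies_view():
    """9 samples: 3 exact copies each of 3 mutually orthogonal unit vectors."""
    basis = np.eye(3)
    X = np.repeat(basis, 3, axis=1)  # 3 features x 9 samples
    return X


class TestSolveLrr:
    def test_block_mass_on_independent_subspaces(self):
        X = orthogonal_copies_view()
        support = knn_adjacency(X, 2)
        sol = solve_lrr(X, support, SolverConfig(lam=0.5))
        assert sol.converged
        A = np.abs(sol.Z)
        block = sum(A[i * 3:(i + 1) * 3, i * 3:(i + 1) * 3].sum() for i in range(3))
        assert block / A.sum() > 0.95

    def test_column_sums_near_one(self):
        rng = np.random.default_rng(1)
        X = spectral_rescale(zscore_features(rng.normal(size=(12, 10))))
        sol = solve_lrr(X, knn_adjacency(X, 4), SolverConfig())
        assert sol.converged
        np.testing.assert_allclose(sol.Z.sum(axis=0), 1.0, atol=10 * 1e-6)

    def test_large_lambda_forces_exact_reconstruction(self):
        # 6 samples on a 2-d subspace of R^4: exactly representable, so a
        # large lambda must drive the error term to (numerical) zero
        rng = np.random.default_rng(2)
        B = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        X = B @ rng.normal(size=(2, 6))
        support = knn_adjacency(X, 5)  # all off-diagonal pairs
        sol = solve_lrr(X, support, SolverConfig(lam=1e3))
        assert sol.converged
        assert np.abs(sol.E).max() < 1e-4
        rel = np.linalg.norm(X - X @ sol.Z) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_support_respected_exactly(self):
        import warnings

        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 8))
        support = knn_adjacency(X, 3)
        with warnings.catch_warnings():
            # truncated run: convergence is irrelevant to the support property
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = solve_lrr(X, support, SolverConfig(max_iter=50))
        assert np.all(sol.Z[~support.mask] == 0.0)
        assert np.all(np.diag(sol.Z) == 0.0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 7))
        support = knn_adjacency(X, 3)
        Z1 = solve_lrr(X, support, SolverConfig()).Z
        Z2 = solve_lrr(X, support, SolverConfig()).Z
        np.testing.assert_array_equal(Z1, Z2)

    def test_non_convergence_warns_not_raises(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 7))
        support = knn_adjacency(X, 3)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            sol = solve_lrr(X, support, SolverConfig(max_iter=3))
        assert not sol.converged
        assert sol.iterations == 3
        assert sol.residuals.shape == (3, 3)


class TestAffinity:
    def test_zero_representation(self):
        W = affinity_from_representation(np.zeros((4, 4))).W
        np.testing.assert_array_equal(W, np.zeros((4, 4)))

    def test_signed_entries_average_absolutely(self):
        Z = np.zeros((3, 3))
        Z[0, 1] = -0.4
        Z[1, 0] = 0.2
        W = affinity_from_representation(Z).W
        assert W[0, 1] == pytest.approx(0.3)
        assert W[1, 0] == pytest.approx(0.3)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(5, 5))
        W = affinity_from_representation(Z).W
        for i in range(5):
            for j in range(5):
                assert W[i, j] == pytest.approx((abs(Z[i, j]) + abs(Z[j, i])) / 2)
        np.testing.assert_array_equal(W, W.T)
        assert np.all(W >= 0)


class TestEstimator:
    def test_fit_exposes_affinity_and_history(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 20))  # samples x features
        est = LocalLowRankRepresentation(k_neighbors=3).fit(X)
        assert est.affinity_.shape == (12, 12)
        np.testing.assert_array_equal(est.affinity_, est.affinity_.T)
        assert est.converged_
        assert est.solution_.residuals.shape[0] == est.n_iter_

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        est = LocalLowRankRepresentation(lam=0.7, k_neighbors=5)
        cloned = clone(est)
        assert cloned.get_params()["lam"] == 0.7
        cloned.set_params(lam=0.2)
        assert cloned.lam == 0.2


class TestOmicsView:
    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            OmicsView(values=np.array([[1.0, np.nan, 0.0]]), sample_ids=list("abc"))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            OmicsView(values=np.zeros((2, 3)), sample_ids=["a", "a", "b"])
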