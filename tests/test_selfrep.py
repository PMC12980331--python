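import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omiclust.io import Config
from omiclust.selfrep import (SelfRepState, admm_solve, embedding_distance,
                              factor_gram, soft_threshold, update_C, update_duals,
                              update_E, update_Z)
from conftest import make_two_subspace_data


class TestSoftThreshold:
    @pytest.mark.parametrize("a,tau,expected", [
        (1.2, 0.5, 0.7),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
    ])
    def test_scalar_values(self, a, tau, expected):
        assert soft_threshold(np.array([a]), tau)[0] == pytest.approx(expected)

    def test_zero_threshold_identity(self, rng):
        A = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(soft_threshold(A, 0.0), A)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones((2, 2)), -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0, 5))
    def test_nonexpansive(self, a, b, tau):
        sa = soft_threshold(np.array([a]), tau)[0]
        sb = soft_threshold(np.array([b]), tau)[0]
        assert abs(sa - sb) <= abs(a - b) + 1e-12


class TestEmbeddingDistance:
    def test_identity_rows(self):
        D = embedding_distance(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(D, [[0, 1], [1, 0]])

    def test_constant_rows_zero(self):
        D = embedding_distance(np.ones((5, 3)))
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_matches_double_loop(self, rng):
        F = rng.standard_normal((5, 3))
        D = embedding_distance(F)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(
                    0.5 * np.sum((F[i] - F[j]) ** 2), abs=1e-10)


class TestUpdates:
    def _state(self, d, n, rng, mu=2.0):
        return SelfRepState(Z=rng.standard_normal((n, n)),
                            E=rng.standard_normal((d, n)),
                            C=rng.standard_normal((n, n)),
                            Q1=rng.standard_normal((d, n)),
                            Q2=rng.standard_normal((n, n)), mu=mu)

    def test_update_Z_zero_inputs(self, rng):
        st_ = SelfRepState.zeros(3, 4, 1.0)
        Z = update_Z(st_, [], np.zeros((4, 4)), 1.0, 1.0, 1.0)
        np.testing.assert_array_equal(Z, 0.0)

    def test_update_Z_diagonal_removed(self):
        st_ = SelfRepState.zeros(3, 4, 1.0)
        st_.C = np.eye(4)
        Z = update_Z(st_, [], np.zeros((4, 4)), 0.0, 0.0, 0.0)
        np.testing.assert_array_equal(Z, 0.0)  # identity minus its diagonal

    def test_update_Z_elementwise_oracle(self, rng):
        n = 4
        st_ = self._state(3, n, rng)
        others = [rng.standard_normal((n, n)) for _ in range(2)]
        D = embedding_distance(rng.standard_normal((n, 2)))
        xi1, xi2, xi3 = 0.3, 0.7, 0.2
        Z = update_Z(st_, others, D, xi1, xi2, xi3)
        for i in range(n):
            for j in range(n):
                a = st_.C[i, j] + st_.Q2[i, j] / st_.mu
                tau = (xi1 + xi2 * sum(abs(o[i, j]) for o in others)
                       + xi3 * D[i, j]) / st_.mu
                want = 0.0 if i == j else np.sign(a) * max(abs(a) - tau, 0.0)
                assert Z[i, j] == pytest.approx(want, abs=1e-12)
        assert np.all(np.diag(Z) == 0.0)

    def test_update_E_exact_representation(self, rng):
        n, d = 5, 3
        st_ = SelfRepState.zeros(d, n, 1e6)
        st_.C = rng.standard_normal((n, n))
        X = rng.standard_normal((d, n)) @ st_.C  # X = XC impossible; build directly
        X = np.zeros((d, n))
        E = update_E(st_, X)
        np.testing.assert_allclose(E, 0.0, atol=1e-12)

    def test_update_E_elementwise_oracle(self, rng):
        d, n = 3, 4
        st_ = self._state(d, n, rng)
        X = rng.standard_normal((d, n))
        E = update_E(st_, X)
        A = X - X @ st_.C + st_.Q1 / st_.mu
        want = np.sign(A) * np.maximum(np.abs(A) - 1.0 / st_.mu, 0.0)
        np.testing.assert_allclose(E, want, atol=1e-12)

    def test_update_C_normal_equations(self, rng):
        d, n = 4, 5
        st_ = self._state(d, n, rng)
        np.fill_diagonal(st_.Z, 0.0)
        X = rng.standard_normal((d, n))
        C = update_C(st_, X, factor_gram(X))
        rhs = X.T @ (X - st_.E + st_.Q1 / st_.mu) + st_.Z - st_.Q2 / st_.mu
        resid = (X.T @ X + np.eye(n)) @ C - rhs
        assert np.max(np.abs(resid)) < 1e-8

    def test_update_C_matches_dense_inverse(self, rng):
        d, n = 5, 5
        st_ = self._state(d, n, rng)
        np.fill_diagonal(st_.Z, 0.0)
        X = rng.standard_normal((d, n))
        C = update_C(st_, X, factor_gram(X))
        rhs = X.T @ (X - st_.E + st_.Q1 / st_.mu) + st_.Z - st_.Q2 / st_.mu
        want = np.linalg.inv(X.T @ X + np.eye(n)) @ rhs
        np.testing.assert_allclose(C, want, atol=1e-9)

    def test_update_C_zero_data(self, rng):
        n = 4
        st_ = self._state(0, n, rng)
        st_.E = np.zeros((0, n))
        st_.Q1 = np.zeros((0, n))
        np.fill_diagonal(st_.Z, 0.0)
        X = np.zeros((0, n))
        C = update_C(st_, X, factor_gram(X))
        np.testing.assert_allclose(C, st_.Z - st_.Q2 / st_.mu, atol=1e-12)

    def test_duals_unchanged_at_feasibility(self, rng):
        d, n = 3, 4
        st_ = SelfRepState.zeros(d, n, 0.5)
        st_.C = rng.standard_normal((n, n))
        st_.Z = st_.C.copy()
        X = rng.standard_normal((d, n))
        st_.E = X - X @ st_.C
        Q1, Q2, _ = update_duals(st_, X, rho=1.2, mu_max=1e8)
        np.testing.assert_allclose(Q1, 0.0, atol=1e-12)
        np.testing.assert_allclose(Q2, 0.0, atol=1e-12)

    def test_mu_geometric_growth_and_cap(self):
        st_ = SelfRepState.zeros(2, 3, 0.1)
        X = np.zeros((2, 3))
        mus = []
        for _ in range(4):
            _, _, st_.mu = update_duals(st_, X, rho=1.2, mu_max=1e8)
            mus.append(st_.mu)
        np.testing.assert_allclose(mus, [0.12, 0.144, 0.1728, 0.20736])
        st_.mu = 9e7
        _, _, mu = update_duals(st_, X, rho=1.2, mu_max=1e8)
        assert mu == 1e8


class TestAdmmSolve:
    def test_zero_data_fixed_point(self):
        cfg = Config(c=2)
        st_, it = admm_solve(np.zeros((3, 5)), [], np.zeros((5, 2)),
                             1.0, 0.0, 0.0, cfg)
        assert it == 1
        np.testing.assert_array_equal(st_.Z, 0.0)
        np.testing.assert_array_equal(st_.E, 0.0)

    def test_residual_below_eps_on_toy_view(self, rng):
        X, _ = make_two_subspace_data(n_per=10, d=12, dim=2, seed=2)
        cfg = Config(c=2)
        st_, it = admm_solve(X, [], np.zeros((X.shape[1], 2)), 0.5, 0.0, 0.0, cfg)
        resid = np.max(np.abs(X - X @ st_.C - st_.E))
        assert it <= cfg.T1
        if it < cfg.T1:
            assert resid < cfg.eps

    def test_diag_zero_invariant(self, rng):
        X, _ = make_two_subspace_data(seed=4)
        cfg = Config(c=2, T1=10)
        st_, _ = admm_solve(X, [], np.zeros((X.shape[1], 2)), 0.5, 0.0, 0.0, cfg)
        assert np.all(np.diag(st_.Z) == 0.0)

    def test_exclusivity_reduces_overlap(self):
        # two views with identical data; alternating solves with a large
        # cross-view penalty should shrink the shared support mass
        X, _ = make_two_subspace_data(n_per=10, d=12, dim=2, seed=5)
        cfg = Config(c=2)
        n = X.shape[1]
        F = np.zeros((n, 2))

        def alternate(xi2):
            Zs = [np.zeros((n, n)), np.zeros((n, n))]
            states = [None, None]
            for _ in range(2):
                for v in range(2):
                    states[v], _ = admm_solve(X, [Zs[1 - v]], F, 0.5, xi2, 0.0,
                                              cfg, state=states[v])
                    Zs[v] = states[v].Z
            return np.abs(Zs[0] * Zs[1]).sum()

        assert alternate(50.0) < alternate(0.0)

    def test_between_cluster_mass_small_on_subspaces(self):
        X, truth = make_two_subspace_data(n_per=15, d=20, dim=3, seed=0)
        cfg = Config(c=2)
        st_, _ = admm_solve(X, [], np.zeros((X.shape[1], 2)), 0.5, 0.0, 0.0, cfg)
        aZ = np.abs(st_.Z)
        between = aZ[truth[:, None] != truth[None, :]].sum()
        assert between / aZ.sum() < 0.2
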