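import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperblock import FitConfig, Hypergraph, fit, fit_best_of
from hyperblock.em import (_EdgeArrays, attribute_elbo, compute_rho, elbo,
                           solve_u_entry, structural_elbo, u_coefficients,
                           update_beta, update_h, update_h_prime,
                           update_u_gamma0, update_w)
from hyperblock.likelihood import (ModelParams, constant_C, total_loglik)
from oracles import (edge_rate_bruteforce, random_hypergraph, random_onehot,
                     random_params)

GOLDEN_RATIO_ROOT = (3 - np.sqrt(5)) / 2


class TestResponsibilities:
    def test_single_community_is_degenerate(self):
        X = random_onehot(4, 3, seed=0)
        u = np.random.default_rng(0).uniform(0.2, 0.8, size=(4, 1))
        beta = np.ones((1, 3))
        assert np.allclose(update_h(X, u, beta), 1.0)
        assert np.allclose(update_h_prime(X, u, beta), 1.0)

    def test_uniform_inputs_give_uniform_responsibilities(self):
        K = 4
        X = random_onehot(3, 2, seed=1)
        u = np.full((3, K), 0.6)
        beta = np.full((K, 2), 1.0 / K)
        assert np.allclose(update_h(X, u, beta), 1.0 / K)

    def test_hand_computed_two_communities(self):
        u = np.array([[0.9, 0.2]])
        beta = np.array([[0.6, 0.3], [0.4, 0.7]])
        h = update_h(None, u, beta)
        # h_{0,z=0,k} = beta_k0 u_0k / sum
        expect = np.array([0.6 * 0.9, 0.4 * 0.2])
        assert np.allclose(h[0, 0], expect / expect.sum())
        hp = update_h_prime(None, u, beta)
        expect_p = np.array([0.6 * 0.1, 0.4 * 0.8])
        assert np.allclose(hp[0, 0], expect_p / expect_p.sum())

    def test_rows_normalize(self, rng):
        u, _, beta = random_params(6, 3, 4, seed=3)
        X = random_onehot(6, 4, seed=3)
        for arr in (update_h(X, u, beta), update_h_prime(X, u, beta)):
            assert np.allclose(arr.sum(axis=2), 1.0, atol=1e-10)


class TestUpdateBeta:
    def test_single_community(self):
        X = random_onehot(5, 3, seed=0)
        u = np.random.default_rng(1).uniform(size=(5, 1))
        h = update_h(X, u, np.ones((1, 3)))
        hp = update_h_prime(X, u, np.ones((1, 3)))
        assert np.allclose(update_beta(X, u, h, hp), 1.0)

    def test_columns_normalize(self):
        u, _, beta = random_params(7, 3, 4, seed=5)
        X = random_onehot(7, 4, seed=5)
        out = update_beta(X, u, update_h(X, u, beta), update_h_prime(X, u, beta))
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-10)
        assert np.all(out >= 0)

    def test_hand_computed_instance(self):
        u = np.array([[0.8, 0.3], [0.2, 0.9]])
        beta = np.array([[0.5, 0.6], [0.5, 0.4]])
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        h = update_h(X, u, beta)
        hp = update_h_prime(X, u, beta)
        num = np.zeros((2, 2))
        for k in range(2):
            for z in range(2):
                for i in range(2):
                    num[k, z] += X[i, z] * h[i, z, k] + (1 - X[i, z]) * hp[i, z, k]
        expected = num / num.sum(axis=0, keepdims=True)
        assert np.allclose(update_beta(X, u, h, hp), expected, atol=1e-12)


class TestUpdateW:
    def test_empty_edge_set_gives_zero(self):
        h = Hypergraph(["a", "b", "c"], [])
        u, w, _ = random_params(3, 2, 0, seed=0)
        assert np.allclose(update_w(h, u, w), 0.0)

    def test_symmetric_nonnegative(self):
        h = random_hypergraph(8, 12, 3, seed=2)
        for seed in range(3):
            u, w, _ = random_params(8, 3, 0, seed=seed)
            out = update_w(h, u, w)
            assert np.allclose(out, out.T)
            assert np.all(out >= 0)

    def test_update_is_stationary_point_of_bound(self):
        h = random_hypergraph(7, 8, 3, seed=4)
        u, w, _ = random_params(7, 2, 0, seed=4)
        rho = compute_rho(h, u, w)
        w_new = update_w(h, u, w)
        eps = 1e-6
        for k in range(2):
            for q in range(k, 2):
                P = np.zeros((2, 2))
                P[k, q] = P[q, k] = 1.0
                g = (structural_elbo(h, u, w_new + eps * P, rho)
                     - structural_elbo(h, u, w_new - eps * P, rho)) / (2 * eps)
                assert abs(g) < 1e-5


class TestSolveU:
    def test_symmetric_coefficients_golden_value(self):
        assert solve_u_entry(1.0, 1.0, 1.0) == pytest.approx(
            GOLDEN_RATIO_ROOT, abs=1e-14)

    def test_degenerate_cases(self):
        assert solve_u_entry(2.0, 0.0, 3.0) == 0.0
        assert solve_u_entry(0.0, 2.0, 3.0) == pytest.approx(0.4)
        assert solve_u_entry(0.0, 0.0, 0.0) == 0.0
        assert solve_u_entry(5.0, 0.0, 0.0) == 0.0

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            solve_u_entry(-1.0, 1.0, 1.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_root_in_unit_interval(self, a, b, c):
        root = solve_u_entry(a, b, c)
        assert 0.0 <= root <= 1.0
        # it solves the quadratic
        resid = a * root**2 - (a + b + c) * root + b
        assert abs(resid) <= 1e-8 * max(a, b, c)


class TestUCoefficients:
    def _instance(self, gamma):
        h = random_hypergraph(6, 6, 3, seed=7)
        u, w, beta = random_params(6, 2, 3, seed=7)
        X = random_onehot(6, 3, seed=7)
        return h, X, ModelParams(u=u, w=w, beta=beta, gamma=gamma)

    def test_gamma_one_drops_structural_terms(self):
        h, X, params = self._instance(gamma=1.0)
        a, b, c = u_coefficients(0, 1, h, X, params)
        assert a == 0.0
        hh = update_h(X, params.u, params.beta)
        assert b == pytest.approx(float((X[0] * hh[0, :, 1]).sum()), rel=1e-12)

    def test_isolated_node_all_attributes_off(self):
        h = Hypergraph([str(i) for i in range(4)], [(0, 1)])
        u, w, beta = random_params(4, 2, 2, seed=1)
        X = np.zeros((4, 2))
        X[:3, 0] = 1.0
        X[:3, 1] = 0.0
        X[3] = 0.0  # node 3: isolated, no attributes on
        params = ModelParams(u=u, w=w, beta=beta, gamma=1.0)
        a, b, c = u_coefficients(3, 0, h, X, params)
        assert a == 0.0 and b == 0.0 and c > 0.0

    def test_matches_termwise_evaluation(self):
        h, X, params = self._instance(gamma=0.4)
        u, w, beta, g = params.u, params.w, params.beta, params.gamma
        C = constant_C(h.N, h.D)
        i, k = 2, 1
        a_exp = (1 - g) * C * sum(u[j, q] * w[k, q]
                                  for j in range(h.N) if j != i for q in range(2))
        b_struct = 0.0
        for e, wt in zip(h.edges, h.weights):
            if i in e:
                lam = edge_rate_bruteforce(e, u, w)
                for j in e:
                    if j != i:
                        for q in range(2):
                            b_struct += wt * u[i, k] * u[j, q] * w[k, q] / lam
        hh = update_h(X, u, beta)
        hp = update_h_prime(X, u, beta)
        b_exp = (1 - g) * b_struct + g * float((X[i] * hh[i, :, k]).sum())
        c_exp = g * float(((1 - X[i]) * hp[i, :, k]).sum())
        a, b, c = u_coefficients(i, k, h, X, params)
        assert a == pytest.approx(a_exp, rel=1e-10)
        assert b == pytest.approx(b_exp, rel=1e-10)
        assert c == pytest.approx(c_exp, rel=1e-10)

    def test_update_entry_is_stationary_point_of_bound(self):
        h, X, params = self._instance(gamma=0.4)
        rho = compute_rho(h, params.u, params.w)
        h_arr = update_h(X, params.u, params.beta)
        hp_arr = update_h_prime(X, params.u, params.beta)
        for (i, k) in [(0, 0), (3, 1), (5, 0)]:
            a, b, c = u_coefficients(i, k, h, X, params)
            root = solve_u_entry(a, b, c)
            eps = 1e-6

            def bound_at(val):
                u2 = params.u.copy()
                u2[i, k] = val
                p2 = ModelParams(u=u2, w=params.w, beta=params.beta,
                                 gamma=params.gamma)
                return elbo(h, X, p2, rho, h_arr, hp_arr)

            g = (bound_at(root + eps) - bound_at(root - eps)) / (2 * eps)
            assert abs(g) < 1e-5


class TestUpdateUGamma0:
    def test_isolated_node_row_zero(self):
        h = Hypergraph([str(i) for i in range(5)], [(0, 1), (1, 2)])
        u, w, _ = random_params(5, 2, 0, seed=2)
        out = update_u_gamma0(h, u, w)
        assert np.allclose(out[4], 0.0)
        assert np.allclose(out[3], 0.0)

    def test_preclip_matches_explicit_evaluation(self):
        h = random_hypergraph(6, 7, 3, seed=8)
        u, w, _ = random_params(6, 2, 0, seed=8)
        C = constant_C(h.N, h.D)
        out = update_u_gamma0(h, u, w)
        for i in range(6):
            for k in range(2):
                num = 0.0
                for e, wt in zip(h.edges, h.weights):
                    if i in e:
                        lam = edge_rate_bruteforce(e, u, w)
                        for j in e:
                            if j != i:
                                for q in range(2):
                                    num += wt * u[i, k] * u[j, q] * w[k, q] / lam
                den = C * sum(u[j, q] * w[k, q]
                              for j in range(6) if j != i for q in range(2))
                expected = min(num / den, 1.0) if den > 0 else 0.0
                assert out[i, k] == pytest.approx(expected, rel=1e-10)

    def test_values_clipped_to_unit_interval(self):
        h = random_hypergraph(6, 20, 3, seed=3)
        # tiny memberships make the multiplicative step overshoot past 1
        u = np.full((6, 2), 0.05)
        w = np.full((2, 2), 0.05)
        out = update_u_gamma0(h, u, w)
        assert np.all(out <= 1.0) and np.all(out >= 0.0)
        assert np.any(out == 1.0)


class TestBoundTightness:
    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_refreshed_bound_equals_objective(self, gamma):
        h = random_hypergraph(8, 8, 3, seed=6)
        u, w, beta = random_params(8, 3, 2, seed=6)
        X = random_onehot(8, 2, seed=6)
        params = ModelParams(u=u, w=w, beta=beta, gamma=gamma)
        rho = compute_rho(h, u, w)
        h_arr = update_h(X, u, beta)
        hp_arr = update_h_prime(X, u, beta)
        bound = elbo(h, X, params, rho, h_arr, hp_arr)
        exact = total_loglik(h, X, params).L_total
        assert bound == pytest.approx(exact, abs=1e-9)


class TestFit:
    def _instance(self, seed=0):
        h = random_hypergraph(20, 40, 3, seed=seed)
        X = random_onehot(20, 3, seed=seed)
        return h, X

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_objective_trajectory_non_decreasing(self, gamma):
        h, X = self._instance()
        cfg = FitConfig(K=3, gamma=gamma, max_iter=80, check_every=1,
                        n_restarts=1, seed=3)
        res = fit(h, X, cfg)
        assert np.all(np.diff(res.objective_trajectory) >= -1e-8)

    def test_constraints_hold_every_iteration(self):
        h, X = self._instance(seed=4)
        violations = []

        def check(it, u, w, beta):
            if not (np.all(u >= 0) and np.all(u <= 1)):
                violations.append(("u", it))
            if not (np.allclose(w, w.T) and np.all(w >= 0)):
                violations.append(("w", it))
            if beta.size and not np.allclose(beta.sum(axis=0), 1, atol=1e-10):
                violations.append(("beta", it))

        cfg = FitConfig(K=2, gamma=0.7, max_iter=60, n_restarts=1, seed=0)
        fit(h, X, cfg, callback=check)
        assert violations == []

    def test_gamma_positive_requires_attributes(self):
        h, _ = self._instance()
        with pytest.raises(ValueError, match="attribute"):
            fit(h, None, FitConfig(K=2, gamma=0.5, seed=0))

    def test_shape_mismatch_rejected(self):
        h, _ = self._instance()
        with pytest.raises(ValueError, match="N"):
            fit(h, random_onehot(5, 2, seed=0),
                FitConfig(K=2, gamma=0.5, seed=0))

    def test_gamma_one_freezes_affinity(self):
        h, X = self._instance(seed=5)
        captured = []
        cfg = FitConfig(K=2, gamma=1.0, max_iter=10, n_restarts=1, seed=1)
        fit(h, X, cfg, callback=lambda it, u, w, beta: captured.append(w.copy()))
        assert all(np.array_equal(captured[0], w) for w in captured)


class TestFitBestOf:
    def test_single_restart_equals_fit(self):
        h = random_hypergraph(12, 20, 3, seed=1)
        cfg = FitConfig(K=2, gamma=0.0, max_iter=50, n_restarts=1, seed=9)
        r1 = fit(h, None, cfg)
        r2 = fit_best_of(h, None, cfg)
        assert np.array_equal(r1.params.u, r2.params.u)
        assert r1.objective == r2.objective

    def test_best_dominates_every_restart(self):
        h = random_hypergraph(12, 20, 3, seed=2)
        cfg = FitConfig(K=2, gamma=0.0, max_iter=50, n_restarts=4, seed=0)
        best = fit_best_of(h, None, cfg)
        for r in range(4):
            single = fit(h, None, FitConfig(K=2, gamma=0.0, max_iter=50,
                                            n_restarts=1, seed=r))
            assert best.objective >= single.objective - 1e-12

    def test_deterministic_given_seed(self):
        h = random_hypergraph(12, 20, 3, seed=3)
        X = random_onehot(12, 2, seed=3)
        cfg = FitConfig(K=2, gamma=0.6, max_iter=40, n_restarts=3, seed=5)
        r1 = fit_best_of(h, X, cfg)
        r2 = fit_best_of(h, X, cfg)
        assert np.array_equal(r1.params.u, r2.params.u)
        assert np.array_equal(r1.params.w, r2.params.w)
        assert r1.objective_trajectory == r2.objective_trajectory
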