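"""Core solver: penalties, IRLS quantities, coordinate updates, fits, tuning."""

import numpy as np
import pytest
from scipy.integrate import quad
from sklearn.linear_model import LogisticRegression

from slslogit.netadj import NetworkConfig, build_network
from slslogit.simulate import SimulationConfig, make_dataset, simulate_response
from slslogit.solver import (PenaltySpec, SolverState, coordinate_update,
                             fit, fit_comparator, lambda1_grid, lambda_max,
                             laplacian_penalty, mcp, objective,
                             soft_threshold, standardize_columns, tune,
                             working_quantities)


def _toy_network(weights_dense):
    import scipy.sparse as sp
    W = np.asarray(weights_dense, dtype=float)
    from slslogit.netadj import AdjacencyNetwork
    return AdjacencyNetwork(weights=sp.csr_array(W), r_c=0.0,
                            config=NetworkConfig(n_obs=10))


class TestMcp:
    def test_zero_and_saturation(self):
        spec = PenaltySpec(0.5, gamma=4.5)
        assert mcp(0.0, spec) == 0.0
        sat = spec.gamma * spec.lambda1
        assert mcp(sat, spec) == pytest.approx(
            spec.gamma * spec.lambda1 ** 2 / 2)
        assert mcp(10 * sat, spec) == mcp(sat, spec)

    def test_against_quadrature_oracle(self):
        lam, g = 0.5, 4.5
        spec = PenaltySpec(lam, gamma=g)
        for t in [0.3, 1.0, 1.7, 2.25, 5.0]:
            val, _ = quad(lambda x: lam * max(1 - x / (g * lam), 0.0), 0, t)
            assert mcp(t, spec) == pytest.approx(val, abs=1e-10)
        assert mcp(1.0, spec) == pytest.approx(0.5 - 1.0 / 9.0, abs=1e-12)

    def test_even_and_monotone(self, rng):
        spec = PenaltySpec(0.3, gamma=5.0)
        t = rng.uniform(-4, 4, 50)
        assert np.allclose(mcp(t, spec), mcp(-t, spec))
        ts = np.sort(np.abs(t))
        assert np.all(np.diff(mcp(ts, spec)) >= -1e-14)


class TestLaplacianPenalty:
    def test_smooth_profiles_cost_nothing(self):
        net = _toy_network([[0, 0.5, 0], [0.5, 0, -0.4], [0, -0.4, 0]])
        # equal betas on the positive edge, opposite signs on the negative
        assert laplacian_penalty(np.array([1.0, 1.0, -1.0]), net, 2.0) == 0.0

    def test_three_node_toy_against_double_loop(self, rng):
        W = np.array([[0, 0.5, -0.2], [0.5, 0, 0.8], [-0.2, 0.8, 0]])
        net = _toy_network(W)
        beta = rng.standard_normal(3)
        lam2 = 1.7
        expected = 0.0
        for m in range(3):
            for k in range(m + 1, 3):
                if W[m, k] != 0:
                    expected += abs(W[m, k]) * (
                        beta[m] - np.sign(W[m, k]) * beta[k]) ** 2
        expected *= lam2
        assert laplacian_penalty(beta, net, lam2) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        net = _toy_network(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            laplacian_penalty(np.zeros(4), net, 1.0)


class TestObjective:
    def test_null_beta_gives_log_two(self, small_problem):
        X, y, net = (small_problem[k] for k in ("X", "y", "net"))
        val = objective(np.zeros(X.shape[1]), X, y, net, PenaltySpec(0.1, 1.0))
        assert val == pytest.approx(np.log(2.0), abs=1e-12)

    def test_zero_penalty_is_mean_nll(self, small_problem, rng):
        X, y = small_problem["X"], small_problem["y"]
        beta = 0.1 * rng.standard_normal(X.shape[1])
        pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
        nll = -np.mean(y * np.log(pi) + (1 - y) * np.log(1 - pi))
        assert objective(beta, X, y, None, PenaltySpec(0.0, 0.0)) == \
            pytest.approx(nll, abs=1e-10)

    def test_random_instance_term_by_term(self, small_problem, rng):
        X, y, net = (small_problem[k] for k in ("X", "y", "net"))
        beta = 0.2 * rng.standard_normal(X.shape[1])
        spec = PenaltySpec(0.15, 0.7, 4.5)
        pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
        expected = -np.mean(y * np.log(pi) + (1 - y) * np.log(1 - pi))
        expected += sum(float(mcp(b, spec)) for b in beta)
        W = net.weights.toarray()
        lap = 0.0
        for m in range(len(beta)):
            for k in range(m + 1, len(beta)):
                if W[m, k] != 0:
                    lap += abs(W[m, k]) * (
                        beta[m] - np.sign(W[m, k]) * beta[k]) ** 2
        # the network quadratic enters at weight lambda2/2 (update convention)
        expected += spec.lambda2 / 2.0 * lap
        got = objective(beta, X, y, net, spec)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_nonbinary_response_rejected(self, small_problem):
        X = small_problem["X"]
        with pytest.raises(ValueError):
            objective(np.zeros(X.shape[1]), X, np.full(X.shape[0], 0.5),
                      None, PenaltySpec(0.1))


class TestSoftThreshold:
    @pytest.mark.parametrize("u,lam,expected", [
        (3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.0, 0.5, 0.0),
    ])
    def test_values(self, u, lam, expected):
        assert soft_threshold(u, lam) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestWorkingQuantities:
    def test_null_beta(self, small_problem):
        X, y = small_problem["X"], small_problem["y"]
        state = SolverState.initialize(X, y)
        assert np.allclose(state.pi, 0.5)
        assert np.allclose(np.abs(state.residual), 2.0)
        assert np.allclose(state.residual, 4.0 * (y - 0.5))

    def test_random_beta_matches_direct_evaluation(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        beta = rng.standard_normal(3)
        state = SolverState.initialize(X, y, beta)
        pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
        assert np.allclose(state.residual, 4.0 * (y - pi))
        assert np.allclose(state.working_response, X @ beta + state.residual)

    def test_saturated_probability_kills_residual(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([1.0, 1.0])
        state = SolverState.initialize(X, y, np.array([40.0]))
        # pi is clipped at 1 - 1e-10, so the residual floor is 4e-10
        assert np.all(np.abs(state.residual) < 1e-8)


class TestCoordinateUpdate:
    def test_unregularized_branch_rescales_by_four(self, rng):
        # lambda2 = 0 and |u| beyond the MCP knot: beta = u / t = 4 u
        X = rng.standard_normal((50, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.uniform(size=50) < 0.5).astype(float)
        spec = PenaltySpec(1e-4, 0.0, 4.5)
        state = SolverState.initialize(X, y, rng.standard_normal(4))
        n = X.shape[0]
        z = 0.25 * (X[:, 0] @ state.residual / n + state.beta[0])
        assert abs(z) > spec.gamma * spec.lambda1 * 0.25  # second branch
        assert coordinate_update(0, state, X, None, spec) == \
            pytest.approx(4.0 * z)

    def test_zero_gradient_gives_zero(self, rng):
        X = np.ones((8, 1)) * np.array([[1.0]])
        X = np.vstack([np.ones((4, 1)), -np.ones((4, 1))])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        state = SolverState.initialize(X, y)
        # X'r = 0 by symmetry, beta = 0 -> u = 0 -> update 0
        assert coordinate_update(0, state, X, None, PenaltySpec(0.1)) == 0.0

    def test_gamma_guard(self):
        with pytest.raises(ValueError, match="gamma"):
            PenaltySpec(0.1, 0.0, gamma=4.0)

    def test_minimizes_univariate_surrogate_grid_oracle(self, rng):
        """Each update is the argmin of its 1-D penalized surrogate."""
        n, p = 30, 6
        for trial in range(100):
            X = rng.standard_normal((n, p))
            X = (X - X.mean(0)) / X.std(0)
            y = (rng.uniform(size=n) < 0.5).astype(float)
            W = rng.standard_normal((p, p)) * (rng.uniform(size=(p, p)) < 0.4)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            np.clip(W, -1, 1, out=W)
            net = _toy_network(W)
            spec = PenaltySpec(float(rng.uniform(0.01, 0.3)),
                               float(rng.uniform(0, 2)),
                               float(rng.uniform(4.2, 8)))
            beta = rng.standard_normal(p) * 0.5
            state = SolverState.initialize(X, y, beta)
            m = int(rng.integers(p))
            got = coordinate_update(m, state, X, net, spec)

            dot = X[:, m] @ state.residual / n

            def surrogate(b):
                val = 0.125 * (b - beta[m]) ** 2 - 0.25 * dot * (b - beta[m])
                val += float(mcp(b, spec))
                for k in range(p):
                    if k != m and W[m, k] != 0:
                        val += spec.lambda2 / 2.0 * abs(W[m, k]) * (
                            b - np.sign(W[m, k]) * beta[k]) ** 2
                return val

            grid = np.linspace(-6, 6, 24001)
            best = grid[np.argmin([surrogate(b) for b in grid])]
            assert surrogate(got) <= surrogate(best) + 1e-9
            assert got == pytest.approx(best, abs=1e-3)


class TestFit:
    def test_null_model_above_lambda_max(self, small_problem):
        X, y = small_problem["X"], small_problem["y"]
        lam_max = lambda_max(X, y)
        res = fit(X, y, None, PenaltySpec(lam_max * 1.0001))
        assert np.all(res.beta == 0.0)
        assert res.converged

    def test_objective_non_increasing_every_fit(self, small_problem):
        X, y, net = (small_problem[k] for k in ("X", "y", "net"))
        for lam1, lam2 in [(0.2, 0.0), (0.05, 0.5), (0.02, 5.0)]:
            res = fit(X, y, net, PenaltySpec(lam1, lam2))
            assert np.all(np.diff(res.objective_path) <= 1e-10)

    def test_matches_l1_logistic_convex_solver(self, rng):
        """gamma -> inf, lambda2 = 0 is the lasso; check vs liblinear."""
        n, p = 50, 20
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta_true = np.zeros(p)
        beta_true[:3] = [1.0, -1.0, 0.5]
        y = simulate_response(X, beta_true, seed=3).astype(float)
        lam1 = 0.05
        res = fit(X, y, None, PenaltySpec(lam1, 0.0, gamma=1e8),
                  tol=1e-8, max_iter=20000)
        ref = LogisticRegression(penalty="l1", C=1.0 / (n * lam1),
                                 solver="liblinear", fit_intercept=False,
                                 tol=1e-10, max_iter=100000).fit(X, y)
        assert np.max(np.abs(res.beta - ref.coef_.ravel())) < 1e-4

    def test_lasso_comparator_equals_gamma_limit(self, small_problem):
        X, y = small_problem["X"], small_problem["y"]
        spec = PenaltySpec(0.05, 0.0, 4.5)
        direct = fit_comparator("lasso", X, y, spec, tol=1e-8)
        limit = fit(X, y, None, PenaltySpec(0.05, 0.0, gamma=1e8), tol=1e-8)
        assert np.max(np.abs(direct.beta - limit.beta)) < 1e-5

    def test_mcp_comparator_identical_to_lambda2_zero(self, small_problem):
        X, y, net = (small_problem[k] for k in ("X", "y", "net"))
        spec = PenaltySpec(0.08, 0.9, 4.5)
        a = fit_comparator("mcp", X, y, spec, net)
        b = fit(X, y, None, PenaltySpec(0.08, 0.0, 4.5))
        assert np.array_equal(a.beta, b.beta)

    def test_enet_without_ridge_equals_lasso(self, small_problem):
        X, y = small_problem["X"], small_problem["y"]
        a = fit_comparator("enet", X, y, PenaltySpec(0.05, 0.0))
        b = fit_comparator("lasso", X, y, PenaltySpec(0.05, 0.0))
        assert np.array_equal(a.beta, b.beta)

    def test_unknown_comparator_rejected(self, small_problem):
        with pytest.raises(ValueError, match="unknown method"):
            fit_comparator("scad", small_problem["X"], small_problem["y"],
                           PenaltySpec(0.1))

    def test_permutation_equivariance(self, small_problem, rng):
        X, y, net = (small_problem[k] for k in ("X", "y", "net"))
        spec = PenaltySpec(0.05, 0.5)
        base = fit(X, y, net, spec, tol=1e-7)
        perm = rng.permutation(X.shape[1])
        from slslogit.netadj import AdjacencyNetwork
        Wp = net.weights.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp
        net_p = AdjacencyNetwork(weights=sp.csr_array(Wp), r_c=net.r_c,
                                 config=net.config)
        res_p = fit(X[:, perm], y, net_p, spec, tol=1e-7)
        # symmetric sign-aware u_m makes the update order-free; the
        # permuted run reaches the same (sign-adjusted) local optimum
        assert set(perm[res_p.support].tolist()) == set(base.support.tolist())
        assert np.allclose(res_p.beta, base.beta[perm], atol=1e-5)

    def test_network_shrinks_duplicate_coefficient_gap(self, rng):
        """|beta_i - beta_j| for two copies of one signal is non-increasing
        in lambda2."""
        n = 300
        x = rng.standard_normal(n)
        X = np.column_stack([x, x + 1e-3 * rng.standard_normal(n),
                             rng.standard_normal((n, 3))])
        X = (X - X.mean(0)) / X.std(0)
        beta_true = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        y = simulate_response(X, beta_true, seed=5).astype(float)
        net = build_network(X, NetworkConfig(n_obs=n))
        gaps = []
        for lam2 in [0.0, 0.1, 1.0, 10.0]:
            res = fit(X, y, net, PenaltySpec(0.02, lam2))
            gaps.append(abs(res.beta[0] - res.beta[1]))
        # non-increasing up to solver tolerance
        assert all(a >= b - 1e-3 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-2 < gaps[0]

    def test_strong_predictor_recovered_with_correct_sign(self, rng):
        """A single effect-2 predictor at n = 500 is selected with the right
        sign in nearly all replicates."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            X = np.random.default_rng(100 + rep).standard_normal((500, 5))
            X = (X - X.mean(0)) / X.std(0)
            beta_true = np.array([2.0, 0, 0, 0, 0])
            y = simulate_response(X, beta_true, seed=rep).astype(float)
            res = fit(X, y, None, PenaltySpec(0.02))
            if res.beta[0] > 0:
                hits += 1
        assert hits / n_rep >= 0.95


class TestTune:
    def test_single_point_grid(self, small_problem):
        sp_ = small_problem
        tr = tune(sp_["X"], sp_["y"], sp_["X_val"], sp_["y_val"],
                  net=sp_["net"], lam1_grid=[0.05], lam2_grid=[0.1])
        assert tr.best_pair == (0.05, 0.1)
        assert len(tr.grid) == 1

    def test_selected_pair_attains_minimum(self, small_problem):
        sp_ = small_problem
        tr = tune(sp_["X"], sp_["y"], sp_["X_val"], sp_["y_val"],
                  net=sp_["net"], lam2_grid=[0.0, 0.5])
        best_idx = tr.grid.index(tr.best_pair)
        assert tr.val_misclassification[best_idx] == \
            tr.val_misclassification.min()

    def test_warm_start_selection_matches_cold_start(self, small_problem):
        sp_ = small_problem
        lam_max_val = lambda_max(sp_["X"], sp_["y"])
        grid = lambda1_grid(lam_max_val, 3)
        kw = dict(net=sp_["net"], lam1_grid=grid, lam2_grid=[0.0, 0.1, 1.0])
        warm = tune(sp_["X"], sp_["y"], sp_["X_val"], sp_["y_val"],
                    warm_start=True, **kw)
        cold = tune(sp_["X"], sp_["y"], sp_["X_val"], sp_["y_val"],
                    warm_start=False, **kw)
        assert warm.best_pair == cold.best_pair

    def test_degenerate_validation_labels_warn(self, small_problem):
        sp_ = small_problem
        with pytest.warns(UserWarning, match="one class"):
            tune(sp_["X"], sp_["y"], sp_["X_val"],
                 np.ones_like(sp_["y_val"]), net=sp_["net"],
                 lam1_grid=[0.1], lam2_grid=[0.0])


class TestStandardize:
    def test_population_scaling(self, rng):
        X = rng.uniform(0, 2, (40, 6))
        Xs, mu, sd = standardize_columns(X)
        assert np.allclose(Xs.mean(0), 0.0, atol=1e-12)
        assert np.allclose((Xs ** 2).mean(0), 1.0, rtol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize_columns(np.column_stack([np.arange(5.0), np.ones(5)]))
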