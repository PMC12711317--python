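"""Optimizer contracts: Newton stationarity, QP KKT, selection behavior,
profiled constant, and the fitted conditional density."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from splinegraph.data import Dataset
from splinegraph.fitter import (
    NodeFitConfig,
    Objective,
    acv_score,
    conditional_density,
    fit_node,
    newton_step_cd,
    profile_constant,
    project_capped_simplex,
    qp_kkt_residual,
    qp_step_theta2,
    select_M,
    select_lambda_theta1,
    solve_qp_box_budget,
)
from splinegraph.model_space import build_node_model, eval_g
from splinegraph.reference import QuadratureRule, fit_reference


def make_objective(data, alpha=0, q=10, seed=0):
    model = build_node_model(data, alpha, q=q, seed=seed)
    rho = fit_reference(data, alpha)
    rule = QuadratureRule.for_node(data, alpha)
    return model, Objective(model, rho, rule)


@pytest.fixture
def toy_objective():
    rng = np.random.default_rng(0)
    data = Dataset.from_array(rng.random((40, 3)))
    return make_objective(data, q=8)


class TestNewton:
    def test_stationarity(self, toy_objective):
        model, obj = toy_objective
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0, 1.0])
        beta, info = newton_step_cd(obj, 1e-4, theta1, theta2)
        assert info["grad_norm"] < 1e-7

    def test_matches_grid_search_on_tiny_problem(self):
        """2-D toy (1 basis coordinate + 1 coefficient) against a direct
        numerical minimization of the same objective."""
        rng = np.random.default_rng(1)
        data = Dataset.from_array(rng.random((12, 2)))
        model, obj = make_objective(data, q=2, seed=0)
        theta1 = obj.theta1_heuristic()
        theta2 = np.zeros(2)
        lam = 1e-3
        beta, info = newton_step_cd(obj, lam, theta1, theta2)

        Z = obj.design(theta1, theta2)
        b = obj.b_vector(theta1, theta2)
        P = obj.penalty(lam, theta1, theta2)

        def F(bt):
            u = -Z @ bt
            m = u.max()
            return (
                m + np.log(np.mean(np.exp(u - m))) + b @ bt + 0.5 * bt @ P @ bt
            )

        from scipy.optimize import minimize

        res = minimize(F, np.zeros(Z.shape[1]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000})
        assert F(beta) <= res.fun + 1e-6

    def test_oversmoothing_limit_flat_estimate(self):
        rng = np.random.default_rng(2)
        data = Dataset.from_array(rng.random((200, 2)))
        model, obj = make_objective(data, q=15, seed=0)
        theta1 = obj.theta1_heuristic()
        theta2 = np.zeros(2)
        beta, _ = newton_step_cd(obj, 1e3, theta1, theta2)
        from splinegraph.model_space import NodeFit

        fit = NodeFit(beta[model.m:], beta[:model.m], theta1, theta2, 1e3, 0.0)
        grid = np.column_stack([np.linspace(0, 1, 50), np.full(50, 0.5)])
        g = eval_g(model, fit, grid)
        # uniform data + huge penalty: only the unpenalized linear contrast
        # remains, and it is small
        assert np.std(g) < 0.05


class TestProfileConstant:
    def test_zero_g(self):
        assert profile_constant(np.zeros(10)) == 0.0

    def test_constant_shift(self):
        assert profile_constant(np.full(7, np.log(2))) == pytest.approx(
            -np.log(2), abs=1e-12
        )

    def test_matches_1d_minimization(self):
        """ς̂ minimizes mean{e^{-ς-g}} + ς, the ς-profile of the
        pseudo-likelihood."""
        rng = np.random.default_rng(3)
        g = rng.standard_normal(50)
        res = minimize_scalar(
            lambda s: np.mean(np.exp(-s - g)) + s, bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert profile_constant(g) == pytest.approx(res.x, abs=1e-6)


class TestProjection:
    def test_projection_properties(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            nk = rng.integers(1, 10)
            th = rng.standard_normal(nk) * 3
            w = rng.uniform(0.5, 2.0, nk)
            M = float(rng.uniform(0.0, 4.0))
            x = project_capped_simplex(th, w, M)
            assert (x >= 0).all()
            assert w @ x <= M + 1e-9
            # projection is idempotent
            assert np.allclose(project_capped_simplex(x, w, M), x, atol=1e-12)

    def test_interior_point_unchanged(self):
        x = project_capped_simplex(np.array([0.1, 0.2]), np.ones(2), 1.0)
        assert np.allclose(x, [0.1, 0.2])


class TestQPStep:
    def test_zero_budget_gives_exact_zero(self, toy_objective):
        model, obj = toy_objective
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0, 1.0])
        beta, _ = newton_step_cd(obj, 1e-4, theta1, theta2)
        d, c = beta[: model.m], beta[model.m:]
        th = qp_step_theta2(obj, c, d, theta1, 1e-4, M=0.0)
        assert np.all(th == 0.0)

    def test_kkt_at_solution(self, toy_objective):
        model, obj = toy_objective
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0, 1.0])
        beta, _ = newton_step_cd(obj, 1e-4, theta1, theta2)
        d, c = beta[: model.m], beta[model.m:]
        for M in (0.5, 2.0, None):
            th = qp_step_theta2(obj, c, d, theta1, 1e-4, M=M, theta2_init=theta2)
            assert qp_kkt_residual(obj, c, d, theta1, 1e-4, th, M) < 1e-5

    def test_matches_constrained_grid_search(self, toy_objective):
        """p=3 toy: 2 free interaction coordinates against a dense feasible
        grid of the true reduced objective."""
        model, obj = toy_objective
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0, 1.0])
        lam = 1e-4
        beta, _ = newton_step_cd(obj, lam, theta1, theta2)
        d, c = beta[: model.m], beta[model.m:]
        M = 1.5
        th = qp_step_theta2(obj, c, d, theta1, lam, M=M, theta2_init=theta2)

        a0 = obj.Phi @ d
        for j, Xi in obj.Xi_main.items():
            a0 = a0 + theta1[j] * (Xi @ c)
        Psi2 = np.column_stack([obj.Xi_int[k] @ c for k in obj.ks])
        bpsi = np.array([(obj.cache.int_b[k] @ c).mean() for k in obj.ks])
        v = np.array([0.5 * lam * (c @ model.Q_int[k] @ c) for k in obj.ks])

        def A2(t):
            u = -a0 - Psi2 @ t
            m = u.max()
            return m + np.log(np.mean(np.exp(u - m))) + (bpsi + v) @ t

        best = np.inf
        grid = np.linspace(0, M, 81)
        for t1 in grid:
            for t2 in grid:
                if t1 + t2 <= M:
                    best = min(best, A2(np.array([t1, t2])))
        assert A2(th[obj.ks]) <= best + 1e-3


class TestSelection:
    def test_lambda_argmin_contract(self, toy_objective):
        model, obj = toy_objective
        cfg = NodeFitConfig(seed=0, refine_theta1=False)
        theta2 = np.array([0.0, 1.0, 1.0])
        lam, th1, beta, info, score = select_lambda_theta1(obj, theta2, cfg)
        grid = cfg.lam_grid()
        assert lam in grid

    def test_pure_noise_selects_heavy_smoothing(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = Dataset.from_array(rng.random((100, 2)))
            model, obj = make_objective(data, q=12, seed=seed)
            cfg = NodeFitConfig(seed=seed, refine_theta1=False)
            theta2 = np.zeros(2)
            lam, *_ = select_lambda_theta1(obj, theta2, cfg)
            grid = cfg.lam_grid()
            hits += lam >= grid[len(grid) // 2]
        assert hits >= 8

    def test_acv_close_to_exact_loo(self):
        """The one-step leave-one-out score tracks exact LOO refitting on a
        small problem."""
        rng = np.random.default_rng(5)
        data = Dataset.from_array(rng.random((30, 2)))
        model, obj = make_objective(data, q=10, seed=0)
        theta1 = obj.theta1_heuristic()
        theta2 = np.zeros(2)
        lam = 1e-2
        beta, info = newton_step_cd(obj, lam, theta1, theta2)
        approx = acv_score(obj, beta, info, theta1, theta2, alpha=1.0)

        # exact LOO refitting
        n = obj.n
        b_rows = obj.b_rows(theta1, theta2)
        Z = obj.design(theta1, theta2)
        losses = []
        for i in range(n):
            rows = np.delete(np.arange(n), i)
            beta_i, _ = newton_step_cd(
                obj, lam, theta1, theta2, beta0=beta, rows=rows
            )
            g_train = Z[rows] @ beta_i
            varsig = profile_constant(g_train)
            g_i = Z[i] @ beta_i
            losses.append(
                np.exp(-varsig - g_i) + varsig + b_rows[i] @ beta_i
            )
        exact = float(np.mean(losses))
        assert approx == pytest.approx(exact, rel=0.1)

    def test_M_grid_only_zero_returns_zero(self, toy_objective):
        model, obj = toy_objective
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0, 1.0])
        beta, _ = newton_step_cd(obj, 1e-4, theta1, theta2)
        d, c = beta[: model.m], beta[model.m:]
        cfg = NodeFitConfig(seed=0)
        M, th, grid = select_M(
            obj, c, d, theta1, 1e-4, cfg, M_grid=np.array([0.0])
        )
        assert M == 0.0
        assert np.all(th == 0.0)


class TestFitNode:
    def test_convergence_flag_contract(self, gaussian_pair_data):
        model, fit = fit_node(
            gaussian_pair_data, 0, NodeFitConfig(seed=0, max_iter=8)
        )
        if fit.converged:
            assert fit.trace[-1]["theta2_rel_change"] < 1e-3

    def test_gaussian_edge_detected(self, gaussian_pair_data):
        model, fit = fit_node(gaussian_pair_data, 0, NodeFitConfig(seed=0))
        assert fit.theta2[1] > 1e-8  # the correlated partner

    def test_row_order_invariance_with_fixed_representers(self):
        rng = np.random.default_rng(8)
        data = Dataset.from_array(rng.random((60, 2)))
        model, obj = make_objective(data, q=60)
        theta1 = obj.theta1_heuristic()
        theta2 = np.array([0.0, 1.0])
        beta, _ = newton_step_cd(obj, 1e-3, theta1, theta2)

        perm = rng.permutation(60)
        data2 = Dataset(data.values[perm], data.kinds, list(data.columns))
        model2 = build_node_model(data2, 0, q=60)
        # use the SAME representers (all rows, permuted order)
        rho2 = fit_reference(data2, 0)
        rule2 = QuadratureRule.for_node(data2, 0)
        obj2 = Objective(model2, rho2, rule2)
        theta1b = obj2.theta1_heuristic()
        beta2, _ = newton_step_cd(obj2, 1e-3, theta1b, theta2)
        from splinegraph.model_space import NodeFit

        fit1 = NodeFit(beta[model.m:], beta[:model.m], theta1, theta2, 1e-3, 0)
        fit2 = NodeFit(beta2[model2.m:], beta2[:model2.m], theta1b, theta2, 1e-3, 0)
        pts = rng.random((20, 2))
        assert np.allclose(
            eval_g(model, fit1, pts), eval_g(model2, fit2, pts), atol=1e-6
        )


class TestConditionalDensity:
    def test_reduces_to_reference_when_g_zero(self, gaussian_pair_data):
        model, fit = fit_node(gaussian_pair_data, 0, NodeFitConfig(seed=0))
        fit.c[:] = 0.0
        fit.d[:] = 0.0
        rho = fit._rho
        nodes, dens = conditional_density(
            model, fit, rho, gaussian_pair_data.values[0]
        )
        rule = QuadratureRule(nodes, np.polynomial.legendre.leggauss(101)[1] / 2)
        ref = rho.density_on_nodes(gaussian_pair_data.values[:1],
                                   __import__("splinegraph.fitter", fromlist=["QuadratureRule"]).QuadratureRule(nodes, rule.weights))[0]
        assert np.allclose(dens, ref, rtol=1e-8)

    def test_normalization_many_conditioning_vectors(self, gaussian_pair_data):
        model, fit = fit_node(gaussian_pair_data, 0, NodeFitConfig(seed=0))
        from splinegraph.model_space import gauss_legendre_01

        nodes, weights = gauss_legendre_01(101)
        rule = QuadratureRule(nodes, weights)
        for i in range(20):
            _, dens = conditional_density(
                model, fit, fit._rho, gaussian_pair_data.values[i], rule
            )
            assert np.sum(rule.weights * dens) == pytest.approx(1.0, abs=1e-8)

    def test_conditional_mean_tracks_truth(self):
        """Bivariate Gaussian: the fitted conditional mean follows the
        closed-form regression line on the unit-interval scale."""
        rng = np.random.default_rng(12)
        n, r = 500, 0.7
        X = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], n)
        data = Dataset.from_array(X)
        model, fit = fit_node(data, 0, NodeFitConfig(seed=0))
        from splinegraph.model_space import gauss_legendre_01

        nodes, weights = gauss_legendre_01(101)
        rule = QuadratureRule(nodes, weights)
        lo0, hi0 = data.ranges[0]
        errs = []
        for i in range(0, n, 25):
            x2_raw = X[i, 1]
            true_mean_raw = r * x2_raw
            _, dens = conditional_density(model, fit, fit._rho,
                                          data.values[i], rule)
            est_mean = np.sum(rule.weights * dens * nodes)
            true_mean = (true_mean_raw - lo0) / (hi0 - lo0)
            errs.append(abs(est_mean - true_mean))
        assert np.mean(errs) < 0.1
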