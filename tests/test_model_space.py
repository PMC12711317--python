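"""Node model construction, evaluation, decomposition, interaction norms."""

import numpy as np
import pytest

from splinegraph import kernels as K
from splinegraph.data import Dataset
from splinegraph.model_space import (
    NodeFit,
    build_node_model,
    decompose_g,
    default_q,
    eval_g,
    interaction_norm,
    interaction_surface,
)


def random_fit(model, seed=0, theta2_scale=1.0):
    rng = np.random.default_rng(seed)
    theta1 = np.zeros(model.p)
    for j in model.continuous:
        theta1[j] = model.q / np.trace(model.Q_main[j])
    theta2 = np.full(model.p, theta2_scale)
    theta2[model.alpha] = 0.0
    return NodeFit(
        c=rng.standard_normal(model.q) * 0.3,
        d=rng.standard_normal(model.m) * 0.3,
        theta1=theta1,
        theta2=theta2,
        lambda1=1e-4,
        M=1.0,
    )


class TestBuildNodeModel:
    def test_full_representer_set_preserves_order(self, small_mixed_data):
        model = build_node_model(small_mixed_data, 0, q=small_mixed_data.n)
        assert np.array_equal(model.representer_idx, np.arange(small_mixed_data.n))

    def test_all_continuous_counts(self):
        rng = np.random.default_rng(0)
        data = Dataset.from_array(rng.random((30, 3)))
        model = build_node_model(data, 0, q=10, seed=1)
        assert model.m == 3
        assert len(model.Q_int) == 2  # interactions with k != alpha only

    def test_seed_determinism(self, small_mixed_data):
        m1 = build_node_model(small_mixed_data, 1, q=10, seed=5)
        m2 = build_node_model(small_mixed_data, 1, q=10, seed=5)
        assert np.array_equal(m1.representer_idx, m2.representer_idx)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.full(20, 3.14), np.arange(20.0)])
        with pytest.raises(ValueError, match="constant"):
            Dataset.from_array(X)

    def test_default_q_scaling(self):
        assert default_q(10) <= 10
        assert default_q(300) == int(np.ceil(10 * 300 ** (2 / 9)))

    def test_kernel_matrix_matches_naive_loops(self):
        rng = np.random.default_rng(3)
        data = Dataset.from_array(rng.random((12, 3)))
        model = build_node_model(data, 0, q=6, seed=0)
        reps = model.representers
        for j in model.continuous:
            naive = np.array(
                [
                    [K.cubic_R1(reps[u, j], reps[v, j]) for v in range(6)]
                    for u in range(6)
                ]
            )
            assert np.allclose(model.Q_main[j], naive, atol=1e-12)
        for k, Q in model.Q_int.items():
            naive = np.array(
                [
                    [
                        K.cubic_kernel(reps[u, 0], reps[v, 0])
                        * K.cubic_kernel(reps[u, k], reps[v, k])
                        for v in range(6)
                    ]
                    for u in range(6)
                ]
            )
            assert np.allclose(Q, naive, atol=1e-12)


class TestEvalG:
    def test_zero_coefficients_give_zero(self, small_mixed_data):
        model = build_node_model(small_mixed_data, 0, q=8, seed=0)
        fit = random_fit(model)
        fit.c[:] = 0.0
        fit.d[:] = 0.0
        assert np.allclose(eval_g(model, fit, small_mixed_data.values), 0.0)

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(11)
        data = Dataset.from_array(rng.random((9, 3)))
        model = build_node_model(data, 0, q=5, seed=0)
        fit = random_fit(model, seed=2)
        X = rng.random((4, 3))
        got = eval_g(model, fit, X)
        reps = model.representers
        for r, x in enumerate(X):
            val = sum(fit.d[v] * (x[v] - 0.5) for v in range(3))
            for u in range(5):
                s = 0.0
                for j in model.continuous:
                    s += fit.theta1[j] * K.cubic_R1(reps[u, j], x[j])
                for k in model.Q_int:
                    s += (
                        fit.theta2[k]
                        / model.weights[k]
                        * K.cubic_kernel(reps[u, 0], x[0])
                        * K.cubic_kernel(reps[u, k], x[k])
                    )
                val += fit.c[u] * s
            assert got[r] == pytest.approx(val, abs=1e-10)

    def test_zero_theta2_leaves_main_effects_only(self, small_mixed_data):
        model = build_node_model(small_mixed_data, 0, q=8, seed=0)
        fit = random_fit(model, theta2_scale=0.0)
        X = small_mixed_data.values.copy()
        g1 = eval_g(model, fit, X)
        # changing x_alpha-free coordinates shifts g only through their own
        # main effects; interactions are off
        comps = decompose_g(model, fit, X)
        assert all(np.allclose(v, 0.0) for v in comps["interaction"].values())


class TestDecomposition:
    def test_components_sum_to_g(self):
        rng = np.random.default_rng(5)
        data = Dataset.from_array(rng.random((25, 4)))
        model = build_node_model(data, 1, q=10, seed=0)
        fit = random_fit(model, seed=3)
        X = rng.random((50, 4))
        comps = decompose_g(model, fit, X)
        total = sum(comps["main"].values()) + sum(comps["interaction"].values())
        assert np.allclose(total, eval_g(model, fit, X), atol=1e-8)

    def test_all_zero_coefficients_zero_components(self, small_mixed_data):
        model = build_node_model(small_mixed_data, 0, q=8, seed=0)
        fit = random_fit(model)
        fit.c[:] = 0
        fit.d[:] = 0
        comps = decompose_g(model, fit, small_mixed_data.values)
        for part in ("main", "interaction"):
            for v in comps[part].values():
                assert np.allclose(v, 0.0)


class TestInteractionNorm:
    def test_zero_theta_gives_zero(self, small_mixed_data):
        model = build_node_model(small_mixed_data, 0, q=8, seed=0)
        fit = random_fit(model, theta2_scale=0.0)
        assert interaction_norm(model, fit, 2) == 0.0

    def test_linear_in_theta(self):
        rng = np.random.default_rng(9)
        data = Dataset.from_array(rng.random((20, 3)))
        model = build_node_model(data, 0, q=8, seed=0)
        fit1 = random_fit(model, seed=4, theta2_scale=1.0)
        fit2 = random_fit(model, seed=4, theta2_scale=2.0)
        n1 = interaction_norm(model, fit1, 1)
        n2 = interaction_norm(model, fit2, 1)
        assert n2 == pytest.approx(2 * n1, rel=1e-10)

    def test_quadrature_refinement_agrees(self):
        rng = np.random.default_rng(13)
        data = Dataset.from_array(rng.random((30, 3)))
        model = build_node_model(data, 0, q=10, seed=0)
        fit = random_fit(model, seed=6)
        coarse = interaction_norm(model, fit, 1, n_grid=21)
        fine = interaction_norm(model, fit, 1, n_grid=201)
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_surface_matches_pointwise_kernel_sum(self):
        rng = np.random.default_rng(17)
        data = Dataset.from_array(rng.random((15, 3)))
        model = build_node_model(data, 0, q=6, seed=0)
        fit = random_fit(model, seed=8)
        s = np.array([0.2, 0.8])
        t = np.array([0.4])
        surf = interaction_surface(model, fit, 1, s, t)
        for a, sv in enumerate(s):
            manual = sum(
                fit.c[u]
                * K.cubic_kernel(model.representers[u, 0], sv)
                * K.cubic_kernel(model.representers[u, 1], t[0])
                for u in range(6)
            ) * fit.theta2[1]
            assert surf[a, 0] == pytest.approx(manual, abs=1e-12)


class TestRescaling:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(21)
        raw = rng.normal(5.0, 3.0, size=(50, 4))
        data = Dataset.from_array(raw)
        assert np.allclose(data.to_original(), raw, atol=1e-12)
        assert data.values.min() >= 0.0 and data.values.max() <= 1.0
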