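import numpy as np
import pytest

import selfrep.model as model_mod
from selfrep import (
    FitDivergenceError,
    GeneIndex,
    Hyperparameters,
    InteractionMatrix,
    build_similarity_graph,
    compute_column_scalars,
    fit,
    gradient_split,
    graph_penalty,
    initialize_U,
    objective,
    predict,
    update_U,
)
from selfrep.simulate import generate
from conftest import random_instance


def zero_X(n: int) -> InteractionMatrix:
    idx = GeneIndex(tuple(f"g{i}" for i in range(n)))
    return InteractionMatrix(np.zeros((n, n)), idx)


def pairwise_graph_penalty(U, S):
    """Brute-force double-sum oracle: 1/2 sum_l sum_ij (U_il - U_jl)^2 S_ij."""
    n = U.shape[0]
    total = 0.0
    for l in range(n):
        for i in range(n):
            for j in range(n):
                total += 0.5 * (U[i, l] - U[j, l]) ** 2 * S[i, j]
    return total


def fd_gradient(X, U, graph, hp, h=1e-6):
    """Centered finite-difference oracle for the objective gradient."""
    g = np.zeros_like(U)
    for l in range(U.shape[0]):
        for i in range(U.shape[1]):
            Up, Um = U.copy(), U.copy()
            Up[l, i] += h
            Um[l, i] -= h
            g[l, i] = (objective(X, Up, graph, hp) - objective(X, Um, graph, hp)) / (2 * h)
    return g


class TestInitializeU:
    def test_uniform(self):
        U = initialize_U(4, Hyperparameters(init_mode="uniform"))
        np.testing.assert_array_equal(U, np.full((4, 4), 0.25))

    def test_dirichlet_deterministic(self):
        hp = Hyperparameters(init_mode="dirichlet", seed=42)
        np.testing.assert_array_equal(initialize_U(3, hp), initialize_U(3, hp))

    @pytest.mark.parametrize("mode", ["uniform", "dirichlet"])
    def test_feasible_and_strictly_positive(self, mode):
        U = initialize_U(6, Hyperparameters(init_mode=mode, seed=1))
        assert U.min() > 0
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-12)

    def test_n_below_two_is_error(self):
        with pytest.raises(ValueError):
            initialize_U(1, Hyperparameters())


class TestObjective:
    def test_zero_X_identity_U(self):
        hp = Hyperparameters(lambda_l2=1.0, beta_graph=0.0)
        assert objective(zero_X(2), np.eye(2), None, hp) == pytest.approx(2.0)

    def test_identity_U_is_perfect_self_representation(self, rng):
        X, _, _ = random_instance(rng, 5)
        hp = Hyperparameters(lambda_l2=0.0, beta_graph=0.0)
        assert objective(X, np.eye(5), None, hp) == pytest.approx(0.0, abs=1e-14)

    def test_known_value_two_by_two(self):
        # X=[[0,1],[1,0]], U=0.5 everywhere: U^T X U = 0.5*ones, residual^2 = 4*0.25
        idx = GeneIndex(("A", "B"))
        X = InteractionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), idx)
        U = np.full((2, 2), 0.5)
        hp = Hyperparameters(lambda_l2=0.0, beta_graph=0.0)
        assert objective(X, U, None, hp) == pytest.approx(1.0)

    def test_beta_zero_matches_no_graph(self, rng):
        X, graph, U = random_instance(rng, 4)
        hp = Hyperparameters(beta_graph=0.0)
        assert objective(X, U, graph, hp) == objective(X, U, None, hp)

    def test_non_finite_is_reported(self):
        hp = Hyperparameters()
        U = np.full((2, 2), np.inf)
        with pytest.raises(FloatingPointError):
            objective(zero_X(2), U, None, hp)


class TestGraphPenalty:
    def test_identity_U_two_nodes(self):
        idx = GeneIndex(("A", "B"))
        g = build_similarity_graph(np.array([[0.0, 1.0], [1.0, 0.0]]), idx)
        # pairwise form: 1/2 * (S_12 + S_21) * ||e1 - e2||^2 = 2
        assert graph_penalty(np.eye(2), g) == pytest.approx(2.0)

    def test_identical_rows_give_zero(self, rng):
        idx = GeneIndex(tuple("ABCD"))
        S = rng.random((4, 4))
        g = build_similarity_graph((S + S.T) / 2, idx)
        U = np.tile(rng.random(4), (4, 1))
        assert graph_penalty(U, g) == pytest.approx(0.0, abs=1e-12)

    def test_trace_equals_pairwise_double_sum(self, rng):
        for _ in range(5):
            idx = GeneIndex(tuple("ABCD"))
            S = rng.random((4, 4))
            g = build_similarity_graph((S + S.T) / 2, idx)
            U = rng.random((4, 4))
            assert graph_penalty(U, g) == pytest.approx(
                pairwise_graph_penalty(U, g.S), abs=1e-10
            )

    def test_nonnegative_on_random_U(self, rng):
        for _ in range(10):
            idx = GeneIndex(tuple("ABCDE"))
            S = rng.random((5, 5))
            g = build_similarity_graph((S + S.T) / 2, idx)
            U = rng.standard_normal((5, 5))
            assert graph_penalty(U, g) >= -1e-10


class TestGradientSplit:
    def test_zero_X_no_graph(self, rng):
        hp = Hyperparameters(lambda_l2=0.5, beta_graph=0.0)
        U = rng.random((3, 3))
        gp, gn = gradient_split(zero_X(3), U, None, hp)
        np.testing.assert_array_equal(gn, 0.0)
        np.testing.assert_allclose(gp, 2 * 0.5 * U)

    def test_all_zero_when_unregularized(self, rng):
        hp = Hyperparameters(lambda_l2=0.0, beta_graph=0.0)
        U = rng.random((3, 3))
        gp, gn = gradient_split(zero_X(3), U, None, hp)
        np.testing.assert_array_equal(gp, 0.0)
        np.testing.assert_array_equal(gn, 0.0)

    def test_parts_nonnegative(self, rng):
        X, graph, U = random_instance(rng, 5)
        gp, gn = gradient_split(X, U, graph, Hyperparameters())
        assert gp.min() >= 0 and gn.min() >= 0

    def test_matches_finite_differences(self, rng):
        hp = Hyperparameters(lambda_l2=0.3, beta_graph=0.2)
        X, graph, U = random_instance(rng, 5)
        gp, gn = gradient_split(X, U, graph, hp)
        fd = fd_gradient(X, U, graph, hp)
        scale = max(1.0, np.abs(fd).max())
        assert np.abs((gp - gn) - fd).max() / scale < 1e-5


class TestColumnScalars:
    def test_uniform_zero_X_closed_form(self):
        # gp = 2*lam/n everywhere, gn = 0 => a_i = n/(2*lam), b_i = 0
        n, lam = 5, 0.25
        hp = Hyperparameters(lambda_l2=lam, beta_graph=0.0)
        U = np.full((n, n), 1.0 / n)
        gp, gn = gradient_split(zero_X(n), U, None, hp)
        a, b = compute_column_scalars(U, gp, gn, hp.eps_div)
        np.testing.assert_allclose(a, n / (2 * lam), rtol=1e-12)
        np.testing.assert_array_equal(b, 0.0)

    def test_zero_grad_neg_gives_zero_b(self, rng):
        U = rng.random((4, 4))
        gp = rng.random((4, 4)) + 0.1
        a, b = compute_column_scalars(U, gp, np.zeros((4, 4)))
        np.testing.assert_array_equal(b, 0.0)

    def test_matches_explicit_two_term_sums(self, rng):
        U = rng.random((2, 2)) + 0.1
        gp = rng.random((2, 2)) + 0.1
        gn = rng.random((2, 2))
        a, b = compute_column_scalars(U, gp, gn)
        for i in range(2):
            a_expect = U[0, i] / gp[0, i] + U[1, i] / gp[1, i]
            b_expect = U[0, i] * gn[0, i] / gp[0, i] + U[1, i] * gn[1, i] / gp[1, i]
            assert a[i] == pytest.approx(a_expect, rel=1e-12)
            assert b[i] == pytest.approx(b_expect, rel=1e-12)


class TestUpdateU:
    def test_zero_X_maps_to_uniform_fixed_point(self, rng):
        n = 6
        hp = Hyperparameters(lambda_l2=2.0 ** -7, beta_graph=0.0)
        U = rng.random((n, n)) + 0.01
        U /= U.sum(axis=0, keepdims=True)
        X = zero_X(n)
        gp, gn = gradient_split(X, U, None, hp)
        a, b = compute_column_scalars(U, gp, gn, hp.eps_div)
        U1 = update_U(U, gp, gn, a, b, hp)
        np.testing.assert_allclose(U1, 1.0 / n, atol=1e-12)
        # and uniform is a fixed point
        gp, gn = gradient_split(X, U1, None, hp)
        a, b = compute_column_scalars(U1, gp, gn, hp.eps_div)
        U2 = update_U(U1, gp, gn, a, b, hp)
        np.testing.assert_allclose(U2, U1, atol=1e-12)

    def test_unit_ratio_leaves_U_unchanged(self, rng):
        # a_i*gn + 1 == a_i*gp + b_i  =>  multiplier is exactly 1
        U = rng.random((3, 3))
        gn = rng.random((3, 3))
        a = np.ones(3)
        gp = gn + 0.5
        b = np.full(3, 1.0 - 0.5)  # a*gp + b = a*gn + 1
        U1 = update_U(U, gp, gn, a, b, Hyperparameters())
        np.testing.assert_allclose(U1, U, rtol=1e-12)

    def test_update_preserves_nonnegativity(self):
        hp = Hyperparameters()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X, graph, U = random_instance(rng, 6)
            gp, gn = gradient_split(X, U, graph, hp)
            a, b = compute_column_scalars(U, gp, gn, hp.eps_div)
            U1 = update_U(U, gp, gn, a, b, hp)
            assert U1.min() >= 0
            assert np.isfinite(U1).all()

    def test_feasibility_drift_small_at_convergence(self):
        # a single step from an arbitrary feasible point can drift; the
        # simplex is only (approximately) restored at fixed points, so the
        # drift bound is asserted on converged runs
        hp = Hyperparameters()
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, graph, _ = random_instance(rng, 12)
            state, trace = fit(X, graph, hp)
            worst = max(worst, np.abs(state.U.sum(axis=0) - 1).max())
        assert worst < 0.05

    def test_renormalize_gives_exact_simplex(self, rng):
        hp = Hyperparameters(renormalize_columns=True)
        X, graph, U = random_instance(rng, 5)
        gp, gn = gradient_split(X, U, graph, hp)
        a, b = compute_column_scalars(U, gp, gn, hp.eps_div)
        U1 = update_U(U, gp, gn, a, b, hp)
        np.testing.assert_allclose(U1.sum(axis=0), 1.0, atol=1e-12)
        assert U1.min() >= 0 and U1.max() <= 1


class TestFit:
    def test_zero_X_converges_to_uniform_with_objective_lambda(self):
        lam = 2.0 ** -7
        hp = Hyperparameters(lambda_l2=lam, beta_graph=0.0)
        state, trace = fit(zero_X(5), None, hp)
        assert trace.converged and trace.n_iter <= 2
        np.testing.assert_allclose(state.U, 0.2, atol=1e-12)
        # ||U||_F^2 at uniform is exactly 1, so J = lambda
        assert trace.objective_values[-1] == pytest.approx(lam, rel=1e-12)

    def test_planted_blocks_without_graph(self, small_instance):
        X, _, _ = small_instance
        state, trace = fit(X, None, Hyperparameters(beta_graph=0.0))
        assert trace.converged
        assert trace.n_iter <= 1000
        assert trace.objective_values[-1] <= trace.objective_values[0]

    def test_planted_blocks_with_graph_monotone_after_first_iter(self, small_instance):
        X, graph, _ = small_instance
        state, trace = fit(X, graph, Hyperparameters())
        assert np.isfinite(trace.objective_values).all()
        diffs = np.diff(trace.objective_values)
        assert (diffs[1:] <= 1e-9).all()

    def test_mismatched_indices_rejected(self, small_instance, rng):
        X, _, _ = small_instance
        idx = GeneIndex(("A", "B"))
        g = build_similarity_graph(np.zeros((2, 2)), idx)
        with pytest.raises(ValueError, match="indices"):
            fit(X, g, Hyperparameters())

    def test_divergence_guard_raises(self, small_instance, monkeypatch):
        X, graph, _ = small_instance
        values = iter(range(10_000))

        def increasing_objective(*args, **kwargs):
            return float(next(values))

        monkeypatch.setattr(model_mod, "objective", increasing_objective)
        hp = Hyperparameters(divergence_patience=3)
        with pytest.raises(FitDivergenceError) as excinfo:
            model_mod.fit(X, graph, hp)
        assert excinfo.value.trace is not None

    def test_kkt_stationarity_at_convergence(self, small_scenario):
        # At a simplex-interior stationary point the gradient is constant
        # within each column (equality-constraint multiplier).
        X, graph, _ = generate(small_scenario)
        state, trace = fit(X, graph, Hyperparameters(tol=1e-10, max_iter=20000))
        grad = state.grad_pos - state.grad_neg
        for i in range(X.n):
            active = state.U[:, i] > 1e-3
            if active.sum() < 2:
                continue
            col = grad[active, i]
            assert col.std() / max(1e-12, np.abs(col).mean()) < 0.05

    def test_large_lambda_drives_uniform_on_zero_X(self):
        hp = Hyperparameters(lambda_l2=100.0, beta_graph=0.0, init_mode="dirichlet", seed=3)
        state, trace = fit(zero_X(6), None, hp)
        np.testing.assert_allclose(state.U, 1.0 / 6, atol=1e-10)

    def test_trace_final_not_above_initial(self, small_instance):
        X, graph, _ = small_instance
        _, trace = fit(X, graph, Hyperparameters())
        assert trace.objective_values[-1] <= trace.objective_values[0]
        assert trace.converged == (trace.final_relative_change < 1e-4)


class TestPredict:
    def test_identity_U_recovers_X(self, small_instance):
        X, _, _ = small_instance
        pred = predict(X, np.eye(X.n))
        np.testing.assert_array_equal(pred.X_hat, X.X)

    def test_zero_X_gives_zero_scores(self, rng):
        U = rng.random((4, 4))
        pred = predict(zero_X(4), U)
        np.testing.assert_array_equal(pred.X_hat, 0.0)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(5):
            X, _, U = random_instance(rng, 6)
            pred = predict(X, U)
            np.testing.assert_allclose(pred.X_hat, pred.X_hat.T, atol=1e-12)
            assert pred.X_hat.min() >= 0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            predict(zero_X(4), rng.random((3, 3)))
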