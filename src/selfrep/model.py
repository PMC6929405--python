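"""Self-representative factorization X ~ U^T X U with graph regularization.

Objective
---------
    J(U) = ||X - U^T X U||_F^2 + lambda * ||U||_F^2 + beta * Tr(U^T L U)

subject to each column of U lying on the probability simplex.  The solver
is a relaxed majorization-minimization scheme: the gradient is split into
non-negative parts grad_pos - grad_neg and each entry is rescaled
multiplicatively, with per-column scalars (a_i, b_i) absorbing the simplex
equality constraint.  Prediction scores are X_hat = U^T X U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GeneIndex, Hyperparameters, InteractionMatrix, SimilarityGraph

__all__ = [
    "ModelState",
    "TrainingTrace",
    "PredictionMatrix",
    "FitDivergenceError",
    "initialize_U",
    "objective",
    "graph_penalty",
    "gradient_split",
    "compute_column_scalars",
    "update_U",
    "fit",
    "predict",
]


class FitDivergenceError(RuntimeError):
    """Raised when the objective keeps increasing beyond the allowed slack."""

    def __init__(self, message: str, trace: "TrainingTrace | None" = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelState:
    """Final representation matrix plus the gradient pieces at that point."""

    U: np.ndarray
    grad_pos: np.ndarray
    grad_neg: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class TrainingTrace:
    objective_values: np.ndarray  # J at t=0 (initial) through the last iterate
    n_iter: int
    converged: bool
    final_relative_change: float


@dataclass(frozen=True)
class PredictionMatrix:
    """Symmetric non-negative score matrix X_hat = U^T X U."""

    X_hat: np.ndarray
    index: GeneIndex

    def score(self, gene_a: str, gene_b: str) -> float:
        i, j = self.index.position(gene_a), self.index.position(gene_b)
        return float(self.X_hat[i, j])


def initialize_U(n: int, hp: Hyperparameters) -> np.ndarray:
    """Feasible strictly-positive start: columns on the simplex.

    ``uniform`` gives the deterministic 1/n matrix; ``dirichlet`` samples
    each column from a symmetric Dirichlet(1) using ``hp.seed``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 genes, got n={n}")
    if hp.init_mode == "uniform":
        return np.full((n, n), 1.0 / n)
    rng = np.random.default_rng(hp.seed)
    U = rng.dirichlet(np.ones(n), size=n).T  # columns on the simplex
    # Dirichlet can underflow to exact zero; nudge and renormalize.
    U = np.maximum(U, 1e-12)
    return U / U.sum(axis=0, keepdims=True)


def graph_penalty(U: np.ndarray, graph: SimilarityGraph) -> float:
    """Tr(U^T L U) for L = D - S; equals the pairwise weighted sum of
    squared row differences of U."""
    LU = graph.degrees[:, None] * U - graph.S @ U
    return float(np.sum(U * LU))


def _check_finite(value: float, term: str) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite objective term: {term} = {value}")
    return value


def objective(
    X: np.ndarray | InteractionMatrix,
    U: np.ndarray,
    graph: SimilarityGraph | None,
    hp: Hyperparameters,
) -> float:
    """Evaluate J(U).  With beta=0 (or graph=None) this is the plain
    self-representation objective."""
    Xm = X.X if isinstance(X, InteractionMatrix) else np.asarray(X, dtype=float)
    R = Xm - U.T @ (Xm @ U)
    fit_term = _check_finite(float(np.sum(R * R)), "||X - U^T X U||_F^2")
    l2_term = _check_finite(hp.lambda_l2 * float(np.sum(U * U)), "lambda*||U||_F^2")
    if graph is not None and hp.beta_graph > 0:
        g_term = _check_finite(hp.beta_graph * graph_penalty(U, graph), "beta*Tr(U^T L U)")
    else:
        g_term = 0.0
    return fit_term + l2_term + g_term


def gradient_split(
    X: np.ndarray | InteractionMatrix,
    U: np.ndarray,
    graph: SimilarityGraph | None,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative split of the gradient of J at U.

    grad_pos = 4 (XU)(U^T X U) + 2 lambda U + 2 beta D U
    grad_neg = 4 (XU) X + 2 beta S U
    """
    Xm = X.X if isinstance(X, InteractionMatrix) else np.asarray(X, dtype=float)
    XU = Xm @ U
    grad_pos = 4.0 * XU @ (U.T @ XU) + 2.0 * hp.lambda_l2 * U
    grad_neg = 4.0 * XU @ Xm
    if graph is not None and hp.beta_graph > 0:
        grad_pos = grad_pos + 2.0 * hp.beta_graph * (graph.degrees[:, None] * U)
        grad_neg = grad_neg + 2.0 * hp.beta_graph * (graph.S @ U)
    if not (np.all(np.isfinite(grad_pos)) and np.all(np.isfinite(grad_neg))):
        raise FloatingPointError("non-finite gradient")
    return grad_pos, grad_neg


def compute_column_scalars(
    U: np.ndarray,
    grad_pos: np.ndarray,
    grad_neg: np.ndarray,
    eps_div: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column scalars a_i = sum_l U_li / gp_li and
    b_i = sum_l U_li * gn_li / gp_li, with the denominator floored at
    ``eps_div``."""
    denom = np.maximum(grad_pos, eps_div)
    a = (U / denom).sum(axis=0)
    b = (U * grad_neg / denom).sum(axis=0)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise FloatingPointError("non-finite column scalars (denominator guard too small?)")
    return a, b


def update_U(
    U: np.ndarray,
    grad_pos: np.ndarray,
    grad_neg: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    hp: Hyperparameters,
) -> np.ndarray:
    """One multiplicative step: U_li *= (a_i gn_li + 1) / (a_i gp_li + b_i)."""
    numer = a[None, :] * grad_neg + 1.0
    denom = np.maximum(a[None, :] * grad_pos + b[None, :], hp.eps_div)
    U_new = U * numer / denom
    if not np.all(np.isfinite(U_new)):
        raise FloatingPointError("non-finite entries after multiplicative update")
    if hp.renormalize_columns:
        U_new = U_new / np.maximum(U_new.sum(axis=0, keepdims=True), hp.eps_div)
        U_new = np.clip(U_new, 0.0, 1.0)
        U_new = U_new / np.maximum(U_new.sum(axis=0, keepdims=True), hp.eps_div)
    return U_new


def fit(
    X: InteractionMatrix,
    graph: SimilarityGraph | None,
    hp: Hyperparameters,
) -> tuple[ModelState, TrainingTrace]:
    """Run the multiplicative-update loop to convergence.

    Stops when the relative objective change drops below ``hp.tol`` (absolute
    change when the previous value is zero), or at ``hp.max_iter``.  Raises
    :class:`FitDivergenceError` if the objective increases by more than
    ``hp.divergence_slack`` (relative) for ``hp.divergence_patience``
    consecutive iterations.
    """
    if graph is not None and graph.index != X.index:
        raise ValueError("interaction matrix and similarity graph use different gene indices")
    n = X.n
    U = initialize_U(n, hp)
    values = [objective(X, U, graph, hp)]
    converged = False
    rel_change = np.inf
    n_bad = 0
    n_iter = 0
    for _ in range(hp.max_iter):
        grad_pos, grad_neg = gradient_split(X, U, graph, hp)
        a, b = compute_column_scalars(U, grad_pos, grad_neg, hp.eps_div)
        U = update_U(U, grad_pos, grad_neg, a, b, hp)
        n_iter += 1
        j_prev = values[-1]
        j_new = objective(X, U, graph, hp)
        values.append(j_new)

        increase = j_new - j_prev
        if increase > hp.divergence_slack * max(1.0, abs(j_prev)):
            n_bad += 1
            if n_bad > hp.divergence_patience:
                trace = TrainingTrace(np.array(values), n_iter, False, float(rel_change))
                raise FitDivergenceError(
                    f"objective increased for {n_bad} consecutive iterations "
                    f"(last {j_prev:.6g} -> {j_new:.6g} at iteration {n_iter})",
                    trace,
                )
        else:
            n_bad = 0

        rel_change = abs(increase) if j_prev == 0 else abs(increase) / abs(j_prev)
        if rel_change < hp.tol:
            converged = True
            break

    grad_pos, grad_neg = gradient_split(X, U, graph, hp)
    a, b = compute_column_scalars(U, grad_pos, grad_neg, hp.eps_div)
    state = ModelState(U=U, grad_pos=grad_pos, grad_neg=grad_neg, a=a, b=b)
    trace = TrainingTrace(
        objective_values=np.array(values),
        n_iter=n_iter,
        converged=converged,
        final_relative_change=float(rel_change),
    )
    return state, trace


def predict(X: InteractionMatrix, U: np.ndarray) -> PredictionMatrix:
    """Score all pairs: X_hat = U^T X U (symmetric, non-negative)."""
    if U.shape != (X.n, X.n):
        raise ValueError(f"U shape {U.shape} does not match X size {X.n}")
    X_hat = U.T @ (X.X @ U)
    X_hat = (X_hat + X_hat.T) / 2.0  # remove floating asymmetry
    return PredictionMatrix(X_hat, X.index)
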