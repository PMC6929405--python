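"""Hyperparameter grid search and one-dimensional sensitivity sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .data import Hyperparameters, InteractionMatrix, SimilarityGraph
from .evaluation import cross_validate

__all__ = ["GridSpec", "grid_search", "sensitivity_sweep", "default_grid"]


def default_grid() -> list[float]:
    """2^-8, 2^-7, ..., 2^4, 2^5."""
    return [2.0 ** k for k in range(-8, 6)]


@dataclass(frozen=True)
class GridSpec:
    lambda_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_grid()))
    beta_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_grid()))

    def __post_init__(self) -> None:
        if not self.lambda_grid or not self.beta_grid:
            raise ValueError("grids must be non-empty")
        if any(v <= 0 for v in self.lambda_grid):
            raise ValueError("lambda grid values must be > 0")
        if any(v < 0 for v in self.beta_grid):
            raise ValueError("beta grid values must be >= 0")
        # canonical order + dedupe makes the search invariant to input order
        object.__setattr__(self, "lambda_grid", tuple(sorted(set(self.lambda_grid))))
        object.__setattr__(self, "beta_grid", tuple(sorted(set(self.beta_grid))))


def grid_search(
    X: InteractionMatrix,
    graph: SimilarityGraph | None,
    grid: GridSpec,
    base_hp: Hyperparameters | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_negative_samples: int | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Evaluate mean CV AUC for every (lambda, beta) and return the argmax.

    Ties break toward the smallest lambda, then the smallest beta (the grids
    are iterated in ascending order and only a strictly better score wins).
    """
    base_hp = base_hp or Hyperparameters()
    rows = []
    best = None  # (mean_auc, lambda, beta)
    for lam in grid.lambda_grid:
        for beta in grid.beta_grid:
            hp = replace(base_hp, lambda_l2=lam, beta_graph=beta)
            report = cross_validate(
                X, graph, hp, n_folds=n_folds, seed=seed,
                n_negative_samples=n_negative_samples,
            )
            rows.append(
                {
                    "lambda": lam,
                    "beta": beta,
                    "mean_auc": report.mean_auc,
                    "ci_halfwidth": report.ci_halfwidth,
                    **{f"fold{i}_auc": a for i, a in enumerate(report.per_fold_auc)},
                }
            )
            if best is None or report.mean_auc > best[0]:
                best = (report.mean_auc, lam, beta)
    table = pd.DataFrame(rows)
    assert best is not None
    return best[1], best[2], table


def sensitivity_sweep(
    X: InteractionMatrix,
    graph: SimilarityGraph | None,
    fixed_param: str,
    fixed_value: float,
    varying_grid: list[float],
    base_hp: Hyperparameters | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_negative_samples: int | None = None,
) -> pd.DataFrame:
    """Sweep one penalty weight while the other is held fixed.

    ``fixed_param`` is ``"lambda"`` or ``"beta"``; the other parameter takes
    each value in ``varying_grid``.  Returns a table of
    (value, mean_auc, ci_halfwidth, per-fold AUCs).
    """
    if fixed_param not in ("lambda", "beta"):
        raise ValueError(f"fixed_param must be 'lambda' or 'beta', got {fixed_param!r}")
    if not varying_grid:
        raise ValueError("sweep grid must be non-empty")
    base_hp = base_hp or Hyperparameters()
    varying_param = "beta" if fixed_param == "lambda" else "lambda"
    rows = []
    for value in varying_grid:
        kwargs = {
            "lambda_l2": fixed_value if fixed_param == "lambda" else value,
            "beta_graph": fixed_value if fixed_param == "beta" else value,
        }
        hp = replace(base_hp, **kwargs)
        report = cross_validate(
            X, graph, hp, n_folds=n_folds, seed=seed,
            n_negative_samples=n_negative_samples,
        )
        rows.append(
            {
                varying_param: value,
                "mean_auc": report.mean_auc,
                "ci_halfwidth": report.ci_halfwidth,
                **{f"fold{i}_auc": a for i, a in enumerate(report.per_fold_auc)},
            }
        )
    return pd.DataFrame(rows)
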