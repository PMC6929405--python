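"""Cross-validation over known interaction pairs and rank-based AUC.

Known pairs are split into equally-sized folds; each fold is masked out of
the training matrix (both orientations), the model is refit, and held-out
pairs are scored against the unknown pairs of the *full* matrix.  The AUC
is the Mann-Whitney statistic with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data import Hyperparameters, InteractionMatrix, SimilarityGraph
from .model import PredictionMatrix, fit, predict

__all__ = [
    "CVFolds",
    "EvaluationReport",
    "make_folds",
    "mask_test_fold",
    "auc_score",
    "cross_validate",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class CVFolds:
    fold_assignments: dict[Pair, int]
    n_folds: int
    seed: int

    def pairs_in_fold(self, fold_id: int) -> list[Pair]:
        if not 0 <= fold_id < self.n_folds:
            raise ValueError(f"fold_id {fold_id} out of range 0..{self.n_folds - 1}")
        return sorted(p for p, f in self.fold_assignments.items() if f == fold_id)


@dataclass(frozen=True)
class EvaluationReport:
    per_fold_auc: tuple[float, ...]
    mean_auc: float
    sd_auc: float
    ci_halfwidth: float  # 95% normal approximation across folds


def make_folds(X: InteractionMatrix, n_folds: int = 5, seed: int = 0) -> CVFolds:
    """Partition the positive pairs into folds whose sizes differ by <= 1.

    Deterministic for a given seed: pairs are canonically sorted, shuffled
    with ``default_rng(seed)``, and assigned round-robin.
    """
    positives = X.positive_pairs()
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive pairs for {n_folds}-fold CV, got {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    assignments = {positives[idx]: i % n_folds for i, idx in enumerate(order)}
    return CVFolds(assignments, n_folds, seed)


def mask_test_fold(
    X: InteractionMatrix, folds: CVFolds, fold_id: int
) -> tuple[InteractionMatrix, list[Pair]]:
    """Zero out both orientations of every pair in the test fold."""
    test_pairs = folds.pairs_in_fold(fold_id)
    X_train = X.X.copy()
    for a, b in test_pairs:
        i, j = X.index.position(a), X.index.position(b)
        X_train[i, j] = X_train[j, i] = 0.0
    return InteractionMatrix(X_train, X.index), test_pairs


def auc_score(
    scores: PredictionMatrix,
    test_pairs: list[Pair],
    negative_pairs: list[Pair],
) -> float:
    """P(score of random positive > score of random negative), ties count 1/2.

    Computed from midranks: AUC = (R_pos - P(P+1)/2) / (P*N) where R_pos is
    the rank sum of the positives in the pooled ranking.
    """
    if not test_pairs or not negative_pairs:
        raise ValueError("both positive and negative pair sets must be non-empty")
    overlap = set(test_pairs) & set(negative_pairs)
    if overlap:
        raise ValueError(f"positive and negative sets overlap: {sorted(overlap)[:3]}")
    pos = np.array([scores.score(a, b) for a, b in test_pairs])
    neg = np.array([scores.score(a, b) for a, b in negative_pairs])
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    rank_sum = ranks[:n_pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cross_validate(
    X: InteractionMatrix,
    graph: SimilarityGraph | None,
    hp: Hyperparameters,
    n_folds: int = 5,
    seed: int = 0,
    n_negative_samples: int | None = None,
) -> EvaluationReport:
    """Fold-masked refit-and-score cross-validation.

    Negatives are all unordered pairs unknown in the *full* matrix (train
    positives belong to neither class).  ``n_negative_samples`` subsamples
    the negatives (seeded) for speed at large scale.
    """
    folds = make_folds(X, n_folds=n_folds, seed=seed)
    negatives = X.unknown_pairs()
    if not negatives:
        raise ValueError("no unknown pairs available as negatives")
    if n_negative_samples is not None and n_negative_samples < len(negatives):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(negatives), size=n_negative_samples, replace=False)
        negatives = [negatives[i] for i in sorted(keep)]

    aucs = []
    for fold_id in range(n_folds):
        X_train, test_pairs = mask_test_fold(X, folds, fold_id)
        state, _ = fit(X_train, graph, hp)
        scores = predict(X_train, state.U)
        aucs.append(auc_score(scores, test_pairs, negatives))

    aucs_arr = np.array(aucs)
    sd = float(aucs_arr.std(ddof=1)) if n_folds > 1 else 0.0
    return EvaluationReport(
        per_fold_auc=tuple(float(a) for a in aucs),
        mean_auc=float(aucs_arr.mean()),
        sd_auc=sd,
        ci_halfwidth=float(1.96 * sd / np.sqrt(n_folds)),
    )
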