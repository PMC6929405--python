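"""Descending ranking of unknown pairs by predicted interaction score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import InteractionMatrix
from .model import PredictionMatrix

__all__ = ["PredictionRanking", "rank_candidates"]


@dataclass(frozen=True)
class PredictionRanking:
    """Ordered (gene_a, gene_b, score) rows: unknown pairs only, scores
    non-increasing, score ties broken by lexicographic pair name."""

    rows: tuple[tuple[str, str, float], ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def rank_candidates(
    X: InteractionMatrix,
    X_hat: PredictionMatrix,
    top_k: int | None = None,
) -> PredictionRanking:
    """Rank pairs unknown in X (X_ij = 0, i != j) by descending score.

    Known pairs and self-pairs never appear; each unordered pair appears
    once.  Returns min(top_k, number of unknown pairs) rows.
    """
    if X_hat.X_hat.shape != X.X.shape:
        raise ValueError("prediction matrix shape does not match interaction matrix")
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    unknown = X.unknown_pairs()
    if not unknown:
        raise ValueError("no unknown pairs to rank")
    scored = [(a, b, X_hat.score(a, b)) for a, b in unknown]
    scored.sort(key=lambda row: (-row[2], row[0], row[1]))
    if top_k is not None:
        scored = scored[:top_k]
    return PredictionRanking(tuple(scored))
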