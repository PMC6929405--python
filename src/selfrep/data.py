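"""Core domain types: gene index, interaction matrix, similarity graph.

All matrices are dense ``float64`` with a shared :class:`GeneIndex`; gene
ordering is lexicographic unless a caller-supplied universe overrides it,
so every derived matrix is reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneIndex",
    "InteractionMatrix",
    "SimilarityGraph",
    "Hyperparameters",
    "build_interaction_matrix",
    "build_similarity_graph",
]


def _check_identifier(gene: str) -> str:
    if not isinstance(gene, str):
        gene = str(gene)
    if gene.strip() == "":
        raise ValueError(f"invalid gene identifier: {gene!r} (empty/whitespace)")
    return gene


@dataclass(frozen=True)
class GeneIndex:
    """Ordered, unique gene identifiers with 0-based positional lookup."""

    genes: tuple[str, ...]
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("GeneIndex requires at least one gene")
        for g in self.genes:
            _check_identifier(g)
        lookup = {g: i for i, g in enumerate(self.genes)}
        if len(lookup) != len(self.genes):
            seen: set[str] = set()
            dups = sorted({g for g in self.genes if g in seen or seen.add(g)})
            raise ValueError(f"duplicate gene identifiers: {dups}")
        object.__setattr__(self, "_lookup", lookup)

    @classmethod
    def from_genes(cls, genes: Iterable[str], *, sort: bool = True) -> "GeneIndex":
        items = [_check_identifier(g) for g in genes]
        if sort:
            items = sorted(set(items))
        return cls(tuple(items))

    @property
    def n(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._lookup

    def position(self, gene: str) -> int:
        return self._lookup[gene]


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric binary adjacency of validated interactions, zero diagonal.

    ``X[i, j] == 1`` marks a validated pair; ``0`` means *unknown*, not
    a confirmed non-interaction.
    """

    X: np.ndarray
    index: GeneIndex

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        n = self.index.n
        if X.shape != (n, n):
            raise ValueError(f"X shape {X.shape} does not match index size {n}")
        if not np.array_equal(X, X.T):
            raise ValueError("X must be exactly symmetric")
        if np.any(np.diag(X) != 0):
            raise ValueError("X must have a zero diagonal")
        if not np.all(np.isin(X, (0.0, 1.0))):
            raise ValueError("X entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.index.n

    def positive_pairs(self) -> list[tuple[str, str]]:
        """Unordered validated pairs as (gene_a, gene_b), gene_a < gene_b."""
        rows, cols = np.nonzero(np.triu(self.X, k=1))
        genes = self.index.genes
        return sorted(
            tuple(sorted((genes[i], genes[j]))) for i, j in zip(rows, cols)
        )

    def unknown_pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs with X_ij = 0 (off-diagonal)."""
        upper = np.triu(np.ones_like(self.X, dtype=bool), k=1) & (self.X == 0)
        rows, cols = np.nonzero(upper)
        genes = self.index.genes
        return [tuple(sorted((genes[i], genes[j]))) for i, j in zip(rows, cols)]

    def n_positives(self) -> int:
        return int(self.X.sum() // 2)


@dataclass(frozen=True)
class SimilarityGraph:
    """Similarity matrix S in [0,1] with degree matrix D and Laplacian L = D - S."""

    S: np.ndarray
    index: GeneIndex

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        n = self.index.n
        if S.shape != (n, n):
            raise ValueError(f"S shape {S.shape} does not match index size {n}")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("S entries must lie in [0, 1]")

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degrees D_ii = sum_j S_ij."""
        return self.S.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def L(self) -> np.ndarray:
        return self.D - self.S


@dataclass(frozen=True)
class Hyperparameters:
    """Optimizer settings.

    ``lambda_l2`` weights the squared-Frobenius penalty on U, ``beta_graph``
    the Laplacian penalty Tr(U^T L U).  ``renormalize_columns`` opts into
    rescaling U's columns to the simplex after each multiplicative update
    (the literal update rule only preserves the column sums approximately).
    """

    lambda_l2: float = 2.0 ** -7
    beta_graph: float = 2.0 ** -5
    tol: float = 1e-4
    max_iter: int = 1000
    eps_div: float = 1e-12
    init_mode: str = "uniform"
    seed: int = 0
    renormalize_columns: bool = False
    divergence_slack: float = 1e-6
    divergence_patience: int = 10

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0:
            raise ValueError(f"lambda_l2 must be >= 0, got {self.lambda_l2}")
        if self.beta_graph < 0:
            raise ValueError(f"beta_graph must be >= 0, got {self.beta_graph}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.eps_div <= 0:
            raise ValueError(f"eps_div must be > 0, got {self.eps_div}")
        if self.init_mode not in ("uniform", "dirichlet"):
            raise ValueError(f"init_mode must be 'uniform' or 'dirichlet', got {self.init_mode!r}")


def build_interaction_matrix(
    pairs: Sequence[tuple[str, str]],
    universe: Iterable[str] | None = None,
) -> InteractionMatrix:
    """Build a symmetric binary interaction matrix from unordered gene pairs.

    Duplicate pairs and reversed orientations collapse to a single entry.
    Self-pairs are dropped with a warning.  The gene universe defaults to
    the genes appearing in ``pairs`` (sorted lexicographically); pass
    ``universe`` to fix it explicitly.
    """
    cleaned: list[tuple[str, str]] = []
    n_self = 0
    for a, b in pairs:
        a, b = _check_identifier(a), _check_identifier(b)
        if a == b:
            n_self += 1
            continue
        cleaned.append((a, b) if a < b else (b, a))
    if n_self:
        warnings.warn(f"dropped {n_self} self-pair(s); the diagonal is fixed at 0")
    if not cleaned:
        raise ValueError("no valid gene pairs after filtering")

    if universe is None:
        index = GeneIndex.from_genes(g for p in cleaned for g in p)
    else:
        index = universe if isinstance(universe, GeneIndex) else GeneIndex.from_genes(universe, sort=False)
        missing = sorted({g for p in cleaned for g in p if g not in index})
        if missing:
            raise ValueError(f"pairs mention genes outside the supplied universe: {missing[:5]}")

    X = np.zeros((index.n, index.n))
    for a, b in cleaned:
        i, j = index.position(a), index.position(b)
        X[i, j] = X[j, i] = 1.0
    return InteractionMatrix(X, index)


def build_similarity_graph(
    S_raw: np.ndarray,
    index: GeneIndex,
    *,
    negative_tol: float = 1e-8,
) -> SimilarityGraph:
    """Validate and canonicalize a raw similarity matrix.

    The matrix is symmetrized as (S + S^T)/2, its diagonal zeroed (a no-op
    on the Laplacian quadratic form), and entries clipped to [0, 1].
    Negative entries beyond ``negative_tol`` are an error rather than being
    silently clipped.
    """
    S = np.asarray(S_raw, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {S.shape}")
    if S.shape[0] != index.n:
        raise ValueError(
            f"similarity matrix size {S.shape[0]} does not match gene index size {index.n}"
        )
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix contains non-finite entries")
    if S.min() < -negative_tol:
        raise ValueError(f"similarity matrix has negative entries (min {S.min():g})")
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    S = np.clip(S, 0.0, 1.0)
    return SimilarityGraph(S, index)
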