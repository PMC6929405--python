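"""Seeded generator of synthetic interaction networks with planted structure.

Genes are partitioned into functional groups.  Interactions are planted
*between* designated partner groups (compensatory-pathway intuition: a
lethal double knockout pairs genes from two redundant pathways), while the
similarity matrix is high *within* groups — so the similarity graph is
informative about the representation structure without directly encoding
the interaction matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    GeneIndex,
    InteractionMatrix,
    SimilarityGraph,
    build_similarity_graph,
)

__all__ = ["SyntheticScenario", "generate", "default_scenario"]

Pair = tuple[str, str]


@dataclass(frozen=True)
class SyntheticScenario:
    n_genes: int = 150
    group_sizes: tuple[int, ...] = (25, 25, 25, 25, 25, 25)
    sl_group_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5))
    p_in: float = 0.3
    p_out: float = 0.01
    sim_signal: float = 0.8
    sim_noise: float = 0.1
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_genes:
            raise ValueError(
                f"group sizes sum to {sum(self.group_sizes)}, expected n_genes={self.n_genes}"
            )
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_out={self.p_out}, p_in={self.p_in}")
        if self.p_in == self.p_out:
            warnings.warn("p_in == p_out: scenario carries no planted signal")
        if not 0 <= self.sim_signal <= 1:
            raise ValueError(f"sim_signal must be in [0, 1], got {self.sim_signal}")
        if self.sim_noise < 0:
            raise ValueError(f"sim_noise must be >= 0, got {self.sim_noise}")
        for g1, g2 in self.sl_group_pairs:
            if g1 == g2:
                raise ValueError(f"partner group pair ({g1},{g2}) must join distinct groups")
            if not (0 <= g1 < self.n_groups and 0 <= g2 < self.n_groups):
                raise ValueError(f"group pair ({g1},{g2}) out of range for {self.n_groups} groups")


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The calibrated default: n=150, 6 groups of 25, 3 partner group-pairs."""
    return SyntheticScenario(seed=seed)


def _group_labels(scenario: SyntheticScenario) -> np.ndarray:
    return np.repeat(np.arange(scenario.n_groups), scenario.group_sizes)


def generate(
    scenario: SyntheticScenario,
) -> tuple[InteractionMatrix, SimilarityGraph, set[Pair]]:
    """Sample (X, S, ground-truth pair set) for a scenario.

    X_ij ~ Bernoulli(p_in) when genes i, j belong to a designated partner
    group pair, Bernoulli(p_out) otherwise; symmetric, zero diagonal.
    S_ij = sim_signal * [same group] + Gaussian(0, sim_noise), clipped to
    [0, 1].  Ground truth is the full designated cross-group pair set.
    Identical seeds yield bitwise-identical outputs.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    width = len(str(n - 1))
    genes = tuple(f"G{i:0{width}d}" for i in range(n))  # zero-padded: lexicographic == positional
    index = GeneIndex(genes)
    labels = _group_labels(scenario)

    partner = {tuple(sorted(p)) for p in scenario.sl_group_pairs}
    designated = np.zeros((n, n), dtype=bool)
    for g1, g2 in partner:
        block = (labels[:, None] == g1) & (labels[None, :] == g2)
        designated |= block | block.T

    P = np.where(designated, scenario.p_in, scenario.p_out)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    draws = rng.random((n, n))
    X = np.zeros((n, n))
    X[upper] = (draws[upper] < P[upper]).astype(float)
    X = X + X.T
    interactions = InteractionMatrix(X, index)

    same_group = (labels[:, None] == labels[None, :]).astype(float)
    S = scenario.sim_signal * same_group
    if scenario.sim_noise > 0:
        noise = np.zeros((n, n))
        noise[upper] = rng.normal(0.0, scenario.sim_noise, size=int(upper.sum()))
        S = S + noise + noise.T
    np.fill_diagonal(S, 0.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    graph = build_similarity_graph(S, index)

    truth: set[Pair] = set()
    rows, cols = np.nonzero(np.triu(designated, k=1))
    for i, j in zip(rows, cols):
        truth.add(tuple(sorted((genes[i], genes[j]))))
    return interactions, graph, truth
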