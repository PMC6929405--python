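import numpy as np
import pytest

from selfrep import (
    GeneIndex,
    Hyperparameters,
    InteractionMatrix,
    build_similarity_graph,
)
from selfrep.simulate import SyntheticScenario, generate


def random_instance(rng: np.random.Generator, n: int):
    """Random symmetric binary X, similarity graph, and feasible U."""
    index = GeneIndex(tuple(f"g{i:02d}" for i in range(n)))
    upper = np.triu(rng.integers(0, 2, size=(n, n)).astype(float), k=1)
    X = InteractionMatrix(upper + upper.T, index)
    S_raw = rng.random((n, n))
    graph = build_similarity_graph((S_raw + S_raw.T) / 2, index)
    U = rng.random((n, n)) + 0.05
    U /= U.sum(axis=0, keepdims=True)
    return X, graph, U


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """Cheap planted-structure scenario for unit tests (n=40)."""
    return SyntheticScenario(
        n_genes=40,
        group_sizes=(10, 10, 10, 10),
        sl_group_pairs=((0, 1), (2, 3)),
        p_in=0.5,
        p_out=0.02,
        sim_signal=0.8,
        sim_noise=0.05,
        seed=7,
    )


@pytest.fixture
def small_instance(small_scenario):
    return generate(small_scenario)


@pytest.fixture
def default_hp():
    return Hyperparameters()
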