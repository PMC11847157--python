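import numpy as np
import pytest

from phyloreps import (
    AlignedFamily,
    DistanceMatrix,
    patristic_matrix,
    simulate_tree,
)
from phyloreps.synthetic_data import SyntheticConfig


@pytest.fixture
def toy_family() -> AlignedFamily:
    return AlignedFamily(
        family_id="toy",
        labels=("A", "B", "C", "D"),
        rows=("AC-D", "ACAD", "GC-D", "GCAD"),
    )


@pytest.fixture
def chain_matrix() -> DistanceMatrix:
    """Chain metric A-B-C-D with unit steps (1D-realizable tree metric)."""
    labels = ("A", "B", "C", "D")
    values = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
    return DistanceMatrix(labels, values, "patristic")


def random_symmetric_matrix(n: int, rng: np.random.Generator, kind: str = "embedding"):
    """A random labelled distance-like matrix (symmetric, zero diagonal)."""
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values[iu] = rng.uniform(0.1, 10.0, size=len(iu[0]))
    values += values.T
    labels = tuple(f"s{i:03d}" for i in range(n))
    return DistanceMatrix(labels, values, kind)


@pytest.fixture(scope="session")
def medium_tree_and_matrix():
    """A 40-leaf simulated tree and its patristic matrix, shared across tests."""
    cfg = SyntheticConfig(seed=11, n_leaves=40)
    tree = simulate_tree(cfg)
    return cfg, tree, patristic_matrix(tree)
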