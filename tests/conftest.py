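import numpy as np
import pytest

from nmqspr.drugset import load_drugs, worked_example_partition
from nmqspr.molgraph import EdgePartition, MolecularGraph


@pytest.fixture(scope="session")
def drugs():
    return load_drugs()


@pytest.fixture(scope="session")
def worked_partition():
    return worked_example_partition()


def cycle_graph(n: int) -> MolecularGraph:
    return MolecularGraph([(str(k), str((k + 1) % n)) for k in range(n)])


def random_partition(rng: np.random.Generator) -> EdgePartition:
    """Random multiset of weight classes with weights in the chemical range."""
    n_classes = int(rng.integers(1, 10))
    counts = {}
    for _ in range(n_classes):
        i, j = sorted(rng.integers(1, 17, size=2).tolist())
        counts[(i, j)] = counts.get((i, j), 0) + int(rng.integers(1, 7))
    return EdgePartition(counts)
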