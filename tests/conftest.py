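import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.seq_io import Alignment, SpecimenRecord
from barcodelim.simulate import SimConfig, generate_dataset


def dm_from_groups(group_sizes, within, between, jitter=0.0, seed=0):
    """Block distance matrix: tight groups, wide between-group distances."""
    rng = np.random.default_rng(seed)
    ids, labels = [], []
    for g, size in enumerate(group_sizes):
        for i in range(size):
            ids.append(f"g{g+1}_{i+1}")
            labels.append(g)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if labels[i] == labels[j] else between
            val = base + (jitter * rng.random() if jitter else 0.0)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(ids, d, "p"), labels


@pytest.fixture
def two_cluster_dm():
    """Two tight clusters (within <= 0.005) separated by ~0.10."""
    dm, _ = dm_from_groups([4, 4], within=0.003, between=0.10,
                           jitter=0.002, seed=1)
    return dm


@pytest.fixture
def tiny_alignment():
    return Alignment([
        SpecimenRecord("a1", "ACGTACGTAC"),
        SpecimenRecord("a2", "ACGTACGTAC"),
        SpecimenRecord("b1", "ACGTTCGAAC"),
    ])


@pytest.fixture(scope="session")
def separated_dataset():
    """One separated-preset dataset with known truth (8 species x 4 tips)."""
    return generate_dataset(
        SimConfig(n_species=8, tips_per_species=4, seed=7), preset="separated")
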