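import numpy as np
import pytest

from skyisland.popgen import (
    GenotypeMatrix,
    PopulationMap,
    SequenceAlignment,
)


@pytest.fixture
def toy_alignment() -> SequenceAlignment:
    """Four 10 bp sequences: two identical pairs differing at two sites."""
    return SequenceAlignment(
        ids=["a1", "a2", "b1", "b2"],
        seqs=["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTTT", "ACGTACGTTT"],
        partitions={"left": (1, 6), "right": (7, 10)},
    )


def genotypes_from_lists(rows, loci=None, ids=None):
    """rows: list per individual of (a, b) tuples."""
    calls = np.array(rows, dtype=np.int64)
    n, L, _ = calls.shape
    return GenotypeMatrix(
        ids or [f"ind{i}" for i in range(n)],
        loci or [f"loc{j}" for j in range(L)],
        calls,
    )


@pytest.fixture
def two_pop_toy():
    """Two populations of two diploids at two loci; simple allele pools."""
    gt = genotypes_from_lists(
        [
            [(100, 102), (200, 200)],
            [(100, 100), (200, 202)],
            [(104, 104), (204, 204)],
            [(104, 106), (204, 204)],
        ]
    )
    popmap = PopulationMap(
        {"ind0": "A", "ind1": "A", "ind2": "B", "ind3": "B"}
    )
    return gt, popmap


@pytest.fixture(scope="session")
def small_world():
    from skyisland.synthetic import WorldConfig, make_world

    return make_world(WorldConfig(nrows=50, ncols=50), seed=11)
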