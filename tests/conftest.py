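import numpy as np
import pytest

from domssr.genotype_io import BandID, BinaryGenotypeMatrix
from domssr.synthetic_data import toy6


@pytest.fixture
def toy():
    """The fixed 6-individual, 5-band worked example (matrix, partition)."""
    return toy6()


def random_binary_matrix(rng, n_individuals, n_bands, p=0.4, n_primers=2):
    """Small random complete-data panel; every band forced present once."""
    values = (rng.random((n_individuals, n_bands)) < p).astype(np.int8)
    for j in np.flatnonzero(values.sum(axis=0) == 0):
        values[rng.integers(n_individuals), j] = 1
    per = max(1, n_bands // n_primers)
    bands = [BandID(f"Q{j // per + 1}", 100 + j) for j in range(n_bands)]
    individuals = [f"ind{i:02d}" for i in range(n_individuals)]
    return BinaryGenotypeMatrix(individuals, bands, values)
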