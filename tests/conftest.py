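import numpy as np
import pytest

from gmint.preprocess import AbundanceMatrix, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_abundance():
    counts = np.array(
        [
            [10, 0, 5, 1],
            [3, 7, 0, 2],
            [1, 1, 2, 4],
        ]
    )
    return AbundanceMatrix(
        values=counts,
        sample_ids=["a", "b", "c"],
        taxon_ids=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def small_genotype(rng):
    values = rng.integers(0, 3, size=(30, 6))
    # guarantee no constant column
    values[0] = 0
    values[1] = 2
    return GenotypeMatrix(
        values=values,
        positions=np.arange(1, 7) * 100,
        snp_ids=[f"snp{j}" for j in range(6)],
        sample_ids=[f"s{i}" for i in range(30)],
    )
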