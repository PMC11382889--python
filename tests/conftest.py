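import numpy as np
import pytest

from valleypop.datamodel import GenotypeTable, make_metadata
from valleypop.simulate import SimulationConfig, make_study_fixture


def random_table(rng, n_samples=8, n_loci=4, n_alleles=5, missing_rate=0.1):
    """Random genotype table for round-trip and oracle tests."""
    calls = 100 + 2 * rng.integers(0, n_alleles, size=(n_samples, n_loci, 2))
    drop = rng.random((n_samples, n_loci)) < missing_rate
    calls[drop] = -1
    samples = [f"s{i:03d}" for i in range(n_samples)]
    loci = [f"L{j}" for j in range(n_loci)]
    return GenotypeTable(samples, loci, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def study_bundle():
    return make_study_fixture(123)


@pytest.fixture
def tiny_two_pop():
    """Four individuals, one locus, two populations — hand-checkable."""
    calls = np.array(
        [
            [[101, 101]],
            [[101, 103]],
            [[103, 103]],
            [[103, 105]],
        ]
    )
    table = GenotypeTable(["a", "b", "c", "d"], ["L1"], calls)
    labels = np.array(["p1", "p1", "p2", "p2"])
    return table, labels
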