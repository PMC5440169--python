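import numpy as np
import pytest

from ncddetect.io import ReferenceGenome
from ncddetect.simulate import SimulationConfig, simulate_mutations, simulate_reference


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        seed=3,
        chrom_lengths={"chr1": 300_000},
        n_samples=10,
        n_genes=8,
        mutations_per_mb=50.0,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return simulate_reference(tiny_config)


@pytest.fixture(scope="session")
def tiny_elements(tiny_bundle):
    return tiny_bundle.elements()


@pytest.fixture(scope="session")
def tiny_mutations(tiny_config, tiny_bundle, tiny_elements):
    return simulate_mutations(tiny_config, tiny_bundle, elements=tiny_elements)


@pytest.fixture
def toy_genome():
    #                0         1         2
    #                0123456789012345678901234
    return ReferenceGenome({"chr1": "TACGTACGTANGTACGTACGTACGT", "chr2": "ACGT" * 10})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
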