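import numpy as np
import pytest
from hypothesis import settings

from cernakit import SimConfig, generate_transcriptome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A small planted circuit used by several module tests."""
    return SimConfig(
        n_mrna=60,
        n_lncrna=5,
        n_target_genes=20,
        sites_per_control_family=10,
        module_size=10,
        n_replicates=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    txome, sequences, truth = generate_transcriptome(small_config)
    return txome, sequences, truth
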