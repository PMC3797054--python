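import numpy as np
import pytest

from dualcap.simulate import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully deterministic toy experiment configuration."""
    return SimConfig(n_genes=60, n_reads=50_000, n_deadenylated=6,
                     n_adenylated=4, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
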