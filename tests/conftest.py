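import numpy as np
import pytest

from pirnapipe import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    return simdata.SimulationConfig(
        seed=7,
        genome_size=60_000,
        n_clusters=5,
        reads_per_sample=5_000,
        n_genes=100,
    )


@pytest.fixture
def small_sim(small_sim_config):
    return simdata.make_genome(small_sim_config)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
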