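import numpy as np
import pytest

from replong.synthetic_data import SimulationConfig, simulate_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20180446)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    """(ref, catalog, annotation) of the default synthetic study."""
    return simulate_reference(sim_config)


def random_seq(rng, n, gc=0.5):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(bases, size=n, p=p).tobytes().decode()
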