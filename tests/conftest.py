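import numpy as np
import pytest

from koisrna.simulate import SimulationConfig, simulate_references


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=11, depth=3000)


@pytest.fixture(scope="session")
def bundle(cfg):
    return simulate_references(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
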