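import numpy as np
import pytest
from hypothesis import settings

from mitorfan import SimConfig, simulate_mitogenome
from mitorfan.genetic_code import TABLE5

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table5():
    return TABLE5


@pytest.fixture(scope="session")
def sim_genome():
    """One default synthetic mitogenome shared across tests."""
    return simulate_mitogenome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def uniform_weights(table5):
    return {c: 1.0 / 62 for c in table5.sense_codons}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, gc=0.35):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=length))
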