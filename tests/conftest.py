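import numpy as np
import pytest

from crawlkit import synth


@pytest.fixture(scope="session")
def std_episode():
    """One standard 3-unit synthetic nerve episode (seed 1), shared read-only."""
    return synth.standard_episode(seed=1)


@pytest.fixture(scope="session")
def default_cycles():
    cycles, truth = synth.gen_cycles(synth.OscillatorSpec(seed=7))
    return cycles, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
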