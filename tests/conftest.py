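import numpy as np
import pytest

from kurasoc.agents import load_reference_agent
from kurasoc.evolution import decode_genome, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_agent():
    """A structurally valid (not evolved) agent decoded from a seeded genome."""
    return decode_genome(random_genome(np.random.default_rng(7)))


@pytest.fixture(scope="session")
def reference_agent():
    """The packaged evolved agent used for all behavioural contrasts."""
    return load_reference_agent()
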