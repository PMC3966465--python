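import numpy as np
import pytest

from amfmtex import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_truth():
    """Full-size noise-free phantom, shared across tests (read-only)."""
    return phantom.generate_phantom()


@pytest.fixture
def random_16x16(rng):
    return rng.uniform(10.0, 200.0, size=(16, 16))
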