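import numpy as np
import pytest

from genalt.fixtures import canonical_world_specs


@pytest.fixture(scope="session")
def worlds():
    """Canonical named worlds with their statements."""
    return canonical_world_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
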