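import numpy as np
import pytest

from gazenoise import build_mapping


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mapping_500():
    """Mapping table for 500-sample windows, shared across tests."""
    return build_mapping(500, seed=0)


@pytest.fixture(scope="session")
def mapping_12():
    """Mapping table for very short (12-sample) windows."""
    return build_mapping(12, reps=800, seed=0)
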