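import numpy as np
import pytest

from wavecline.simulate import ShoreSimConfig, simulate_shore


@pytest.fixture(scope="session")
def default_shore():
    """One default synthetic study, shared read-only across tests."""
    return simulate_shore(ShoreSimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
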