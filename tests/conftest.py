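import numpy as np
import pytest

from vssr.forward import HeadModel, default_sensor_array


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def sensors(head):
    """Full 204-channel helmet."""
    return default_sensor_array(head=head)


@pytest.fixture(scope="session")
def sensors_small(head):
    """Reduced 48-channel helmet for simulation-heavy tests."""
    return default_sensor_array(n_sites=24, head=head)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
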