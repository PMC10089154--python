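import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netspread import generate_topology_set

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def topologies():
    """The default set of 17 habitat networks (1 lattice + 8 partial + 8 random)."""
    return generate_topology_set(seed=1)


@pytest.fixture(scope="session")
def lattice(topologies):
    return topologies[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
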