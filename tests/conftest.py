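import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import temporal_egt as te

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_dist():
    """The near-uniform activity density f(a) = 1000/999 on [0.001, 1]."""
    return te.ActivityDistribution.uniform(0.001, 1.0)


@pytest.fixture(scope="session")
def coordination_game():
    """2x2 bistable coordination game used in the moment-agreement runs."""
    return te.PayoffMatrix.from_entries([[1.0, 0.0], [0.0, 0.5]])


def random_simplex(rng, n):
    return rng.dirichlet(np.ones(n))
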