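import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from klcontrol import DiscreteDistribution, make_pd_fixture

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def pd_game_exact():
    """The 9-state prisoner's-dilemma game with no reward floor."""
    return make_pd_fixture(floor=0.0).game


@pytest.fixture(scope="session")
def pd_game():
    """The same game with the default tiny floor (finite risks throughout)."""
    return make_pd_fixture().game


def random_distribution(rng: np.random.Generator, n: int,
                        labels=None) -> DiscreteDistribution:
    """Strictly positive random distribution over n states."""
    w = rng.dirichlet(np.full(n, 0.5)) + 1e-12
    return DiscreteDistribution(labels or [f"s{i}" for i in range(n)], w,
                                renormalize=True)
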