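import numpy as np
import pytest
from hypothesis import settings

from switchpool import (
    FeedbackParameters,
    PoolConfig,
    SwitchParameters,
    build_generator,
    build_rate_map,
    dominant_mode,
    enumerate_states,
    pon_curve,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nominal():
    return SwitchParameters.nominal()


@pytest.fixture(scope="session")
def space55():
    return enumerate_states(55)


@pytest.fixture(scope="session")
def gen55(nominal, space55):
    return build_generator(nominal, space55)


@pytest.fixture(scope="session")
def summary55(gen55):
    return dominant_mode(gen55, method="sparse")


@pytest.fixture(scope="session")
def sol55(nominal):
    """Transient master-equation solution at the nominal parameters."""
    return pon_curve(nominal, B=55)


@pytest.fixture(scope="session")
def pool_cfg():
    return PoolConfig(N0=1_000_000, Nd=1_000)


@pytest.fixture(scope="session")
def feedback_nominal():
    return FeedbackParameters.nominal()


@pytest.fixture(scope="session")
def rate_map55(feedback_nominal):
    return build_rate_map(feedback_nominal, B=55, n_points=40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
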