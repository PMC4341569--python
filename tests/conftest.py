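import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig1_result():
    """The 120-s two-population reference trial (shared: it is expensive)."""
    from sleepwake.experiments import fig1_experiment

    return fig1_experiment(seed=1)


@pytest.fixture(scope="session")
def fig4_stability():
    from sleepwake.experiments import fig4_stability_experiment

    return fig4_stability_experiment(seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
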