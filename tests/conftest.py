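import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130912)


@pytest.fixture(scope="session")
def default_study():
    """One generated study under the default conditions, shared read-only."""
    from oriclass.synthetic_study import SimulationConfig, generate_study

    return generate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """A noise-free study: every downstream stage should be exact on it."""
    from oriclass.synthetic_study import SimulationConfig, generate_study

    cfg = SimulationConfig(seed=5, noise_sd=0.0, titration_noise_sd=0.0)
    return generate_study(cfg)
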