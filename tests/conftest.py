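import numpy as np
import pytest

from slowrl.task import SessionConfig, build_session
from slowrl.simulate import simulate_choices


@pytest.fixture(scope="session")
def config():
    return SessionConfig()


@pytest.fixture(scope="session")
def session(config):
    return build_session(config, 123, "p1")


@pytest.fixture(scope="session")
def base_params():
    """Plausible learner parameters in the empirically typical range."""
    return dict(kappa=6.0, c=6.0, sigma=42.0, alpha=0.6)


@pytest.fixture(scope="session")
def sim_log(session, base_params):
    """One simulated participant log from the one-learning-rate model."""
    return simulate_choices("1LR", base_params, session, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
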