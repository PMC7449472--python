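import pytest
from hypothesis import HealthCheck, settings

from coiltox import SyntheticConfig, generate_fleet, generate_sessions, summarize_fleet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(seed=7, noise_sigma=0.0, outlier_rate=0.0)


@pytest.fixture(scope="session")
def fleet(default_config):
    return generate_fleet(default_config)


@pytest.fixture(scope="session")
def noisy_study(default_config, fleet):
    """A 12-device x 4-replicate study at 20% multiplicative noise."""
    sessions, truth = generate_sessions(fleet, default_config)
    return sessions, truth, summarize_fleet(sessions)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config, fleet):
    sessions, truth = generate_sessions(fleet, noiseless_config)
    return sessions, truth, summarize_fleet(sessions)
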