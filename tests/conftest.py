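import pytest
from hypothesis import HealthCheck, settings

import cmcvoi

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return cmcvoi.load_default_config()


@pytest.fixture(scope="session")
def psa20(cfg):
    """A shared 20,000-draw PSA run reused across the stochastic tests."""
    return cmcvoi.run_psa(cfg, n_draws=20_000, seed=11)
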