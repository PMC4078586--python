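import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nephqc import GeneratorConfig, generate_campaign
from nephqc.presets import published_cf_model
from nephqc.synthetic import generate_from_two_step

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_campaign():
    """A default-condition synthetic campaign: 65 pairs, sigma=0.3."""
    return generate_campaign(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def compatible_campaign():
    """Noiseless campaign exactly consistent with the sequential
    richards-log CF + log-log conversion model (unit log-log slope, so
    both stages are simultaneously exactly specified)."""
    return generate_from_two_step(published_cf_model("2a"), a=2.0, b=1.0, n=65, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
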