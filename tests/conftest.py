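import pytest
from hypothesis import HealthCheck, settings

from mitochar.synthetic_data import SimulationConfig, generate_mitogenome

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_table():
    from mitochar.io_formats import reference_feature_table
    return reference_feature_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One seeded synthetic mitogenome shared across tests."""
    return generate_mitogenome(SimulationConfig(seed=11))
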