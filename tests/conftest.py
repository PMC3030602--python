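import pytest
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
def fixtures():
    from mirpath.synthetic_data import load_fixtures

    return load_fixtures()


@pytest.fixture(scope="session")
def desk_study():
    """One shared desk-scale simulated study (planted pathway, seed 11)."""
    from mirpath.synthetic_data import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig.desk(seed=11))
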