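import pytest
from hypothesis import HealthCheck, settings

from mangrofate import build_scenario, make_toy_catchment, run_simulation

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catchment():
    return make_toy_catchment()


@pytest.fixture(scope="session")
def runs_8d(catchment):
    """All four management scenarios over eight tidal days (shared)."""
    out = {}
    for name in ("SC1", "SC2", "SC3", "NonEco"):
        scenario = build_scenario(name, catchment, duration=8 * 86400.0)
        out[name] = run_simulation(scenario)
    return out


@pytest.fixture(scope="session")
def run_sc1_30d(catchment):
    """The baseline scenario over a full month (shared)."""
    return run_simulation(build_scenario("SC1", catchment))
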