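import pytest
from hypothesis import HealthCheck, settings

from schelling_influx import ModelParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def table1_params() -> ModelParams:
    """The reference stochastic scenario (default entry rate)."""
    return ModelParams()


@pytest.fixture
def small_params() -> ModelParams:
    """A miniature city for fast behavioural tests."""
    return ModelParams(
        M=4, n_residents=40, g=0.05, n_iterations=30, seed=11,
    )
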