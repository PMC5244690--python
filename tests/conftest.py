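import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from factmams import AllocationRatios, EffectScenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def balanced() -> AllocationRatios:
    return AllocationRatios(1.0, 1.0)


@pytest.fixture
def case_study() -> dict:
    """Osteoarthritis physiotherapy trial parameters: WOMAC change endpoint."""
    return {"delta": 28.0, "delta0": 7.0, "sigma": 50.0, "alpha": 0.05}


@pytest.fixture
def additive_scenario() -> EffectScenario:
    """Interesting effect on A, uninteresting on B, additive combination."""
    return EffectScenario(0.0, 0.5, 0.1, 0.6, 1.0, delta=0.5, delta0=0.1)


def three_se(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
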