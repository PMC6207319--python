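import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from blinksim import LIFParams, SimulationClock, simulate_lif


@pytest.fixture(scope="session")
def burst_bimodal_sample():
    """A variable-threshold LIF run in the burst-plus-prolonged regime.

    Threshold trough a - k = 0.15 with period 9 s; the distribution has
    a burst peak below 1 s and a prolonged-interval peak near 7 s.
    """
    params = LIFParams(c=0.7, k=0.85, a=1.0, tau=9.0)
    return params, simulate_lif(params, SimulationClock(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
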