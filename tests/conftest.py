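import pytest
from hypothesis import settings, HealthCheck

import gsmeth as gm

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_planted():
    """Paired dataset with a clearly recoverable planted subset."""
    params = gm.SimulationParams(n_probes=2000, n_signal=50, seed=1)
    g, m, design, truth = gm.generate_paired_dataset(params)
    return params, g, m, design, truth


@pytest.fixture(scope="session")
def small_null():
    """Paired dataset with no planted signal and no modality offset."""
    params = gm.SimulationParams(n_probes=2000, n_signal=0, modality_offset=0.0, seed=2)
    g, m, design, truth = gm.generate_paired_dataset(params)
    return params, g, m, design, truth
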