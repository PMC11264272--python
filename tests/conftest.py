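import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: inverse temperature used throughout the examples (kT at 300 K, rounded
#: the way thresholds are usually quoted)
BETA = 1.6775


@pytest.fixture
def beta() -> float:
    return BETA


@pytest.fixture
def gaussian_works():
    """Crooks-consistent Gaussian work pairs with known ΔG = 2 kcal/mol."""
    from neqfe import gaussian_work_pairs

    return gaussian_work_pairs(2.0, 1.0, BETA, 300, 300, seed=1)


@pytest.fixture
def benchmark_df():
    from neqfe import benchmark_table

    return benchmark_table(n_molecules=589, bias=1.0, seed=11)
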