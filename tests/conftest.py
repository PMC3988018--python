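import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmtpeaks import CMTParams, SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def study_params() -> CMTParams:
    """Analysis parameters matched to the simulator's default depth: the
    supported-height threshold sits between background (coverage 2) and a
    fold-10 peak (coverage ~20), the shrink cutoff at twice the background
    mean."""
    return CMTParams(
        fragment_length=200,
        min_region=100,
        max_region=2000,
        cutoff=4.0,
        min_supported_reads=15.0,
        k_fold=2.0,
    )


@pytest.fixture
def one_peak_config() -> SimulationConfig:
    """Default-depth simulation with a single 300-bp fold-10 peak."""
    return SimulationConfig(planted_peaks=((500_000, 300, 10.0),), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140415)
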