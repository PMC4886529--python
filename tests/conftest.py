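import numpy as np
import pytest

from ringmig import (
    RingGeometry,
    SegmentationConfig,
    SimulationParams,
    simulate_tracks,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def nominal_ring():
    return RingGeometry(center=(0.0, 0.0), radius=50.0)


@pytest.fixture(scope="session")
def small_ensemble():
    """30 default-parameter tracks with ground truth (shared, read-only)."""
    params = SimulationParams(seed=0)
    ts, truth = simulate_tracks(params, 30)
    return params, ts, truth


@pytest.fixture(scope="session")
def default_seg_config():
    return SegmentationConfig(seed=0)
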