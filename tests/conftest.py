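import numpy as np
import pytest

from hippoclust.config import CohortConfig, GridSpec, default_config


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return default_config(seed=7)


@pytest.fixture(scope="session")
def small_cfg(default_cfg) -> CohortConfig:
    """Scaled-down cohort (24 complete subjects, T=60) for fast unit tests."""
    return default_cfg.replace(
        n_enrolled=30,
        n_complete=24,
        cluster_sizes=[12, 12],
        grid={
            "dimensions": [24, 24, 12],
            "voxel_size_mm": 2.0,
            "n_timepoints": 60,
            "tr_seconds": 2.0,
        },
    )


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec(dimensions=(24, 24, 12), n_timepoints=60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
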