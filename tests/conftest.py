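import numpy as np
import pandas as pd
import pytest

from gaphunt.datatypes import BetaMatrix
from gaphunt.simulate import SimConfig, simulate_benchmark_dataset


@pytest.fixture
def six_values():
    """Worked example: three clusters with gaps after sorted indices 2 and 4."""
    return np.array([0.10, 0.12, 0.13, 0.55, 0.57, 0.95])


@pytest.fixture
def small_beta(six_values):
    """Two probes: the worked example and a constant probe."""
    data = pd.DataFrame(
        [six_values, np.full(6, 0.4)],
        index=["probe_gap", "probe_flat"],
        columns=[f"S{i}" for i in range(6)],
    )
    return BetaMatrix(data)


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down benchmark dataset shared across tests."""
    cfg = SimConfig(
        n_samples=120,
        seed=7,
        n_gap_probes=60,
        n_cloud_probes=10,
        n_outlier_probes=10,
        n_flat_probes=60,
    )
    beta, truth = simulate_benchmark_dataset(cfg)
    return cfg, beta, truth
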