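import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from procjs import SimulationConfig, build_marrays, simulate_dataset
from procjs.io import micro_histories


@pytest.fixture(scope="session")
def micro():
    """Hand-checkable T = 3 encounter histories."""
    return micro_histories()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset (T = 5, 50 releases/occasion, rho = 0.5)."""
    cfg = SimulationConfig(T=5, releases_per_occasion=50, rho=0.5, seed=20260101)
    hist, rates = simulate_dataset(cfg)
    return hist, rates


@pytest.fixture(scope="session")
def small_marrays(small_dataset):
    hist, _ = small_dataset
    return build_marrays(hist)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
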