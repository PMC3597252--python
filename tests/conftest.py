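import numpy as np
import pandas as pd
import pytest

from coastbalance.synthetic_data import BasinConfig, GroundTruth, default_basins


@pytest.fixture(scope="session")
def basins():
    return default_basins()


@pytest.fixture(scope="session")
def bothnian_bay(basins):
    return basins[0]


@pytest.fixture
def quiet_truth():
    """Noise-free generative truth for exact-recovery tests."""
    return GroundTruth(seed=11, noise_cv=0.0)


@pytest.fixture
def noisy_truth():
    """Default-noise generative truth (20% multiplicative CV)."""
    return GroundTruth(seed=11)


@pytest.fixture
def constant_flow():
    """One year of constant 1000 m^3 s^-1 daily flow (non-leap year)."""
    idx = pd.date_range("1995-01-01", "1995-12-31", freq="D")
    return pd.Series(1000.0, index=idx)
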