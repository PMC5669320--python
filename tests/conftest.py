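import numpy as np
import pytest

from tfstest import ListenerModel, StaircaseConfig


@pytest.fixture
def af_config() -> StaircaseConfig:
    """Standard adaptive-frequency track: phi=180, start 200 Hz,
    factors 1.4/1.2/1.1, 30-Hz floor, 8 reversals."""
    return StaircaseConfig.tfs_af()


@pytest.fixture
def lf_config() -> StaircaseConfig:
    """Standard adaptive-IPD track at 250 Hz: start 180 deg,
    factors 1.95/1.56/1.25, 180-deg ceiling."""
    return StaircaseConfig.tfs_lf()


@pytest.fixture
def steep_listener() -> ListenerModel:
    """Steep, lapse-free observer: staircase estimates should sit close to
    the 70.7%-correct frequency."""
    return ListenerModel(f_max=1000.0, beta=6.0, lapse=0.0, phi_half=30.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
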