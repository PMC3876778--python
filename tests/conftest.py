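import numpy as np
import pytest

from mhrsim import NONAPOPTOTIC_FIBROBLAST, T98G, RadiationParams, ThermalParams


@pytest.fixture
def nonapoptotic() -> RadiationParams:
    """Repair-competent fibroblast parameter set (alpha=1.1, c_r=100, ...)."""
    return NONAPOPTOTIC_FIBROBLAST


@pytest.fixture
def t98g() -> RadiationParams:
    return T98G


@pytest.fixture
def thermal() -> ThermalParams:
    return ThermalParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
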