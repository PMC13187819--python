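import numpy as np
import pytest

from edofscope import OpticalConfig, SensorConfig, flat_mask


@pytest.fixture(scope="session")
def small_optics():
    """Reduced pupil sampling: same physics, fast FFTs."""
    return OpticalConfig(pupil_grid_size=128, psf_window_px=31)


@pytest.fixture(scope="session")
def metrology_optics():
    """Full-accuracy optical configuration (package defaults)."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def fine_sensor():
    """16-bit quantization + pedestal: resolves the 4 e- read noise."""
    return SensorConfig(adc_bits=16, black_level_e=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_flat_mask(small_optics):
    return flat_mask(small_optics.pupil_grid_size)
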