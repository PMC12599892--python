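import numpy as np
import pytest

from spheromech import brillouin, synth


@pytest.fixture(scope="session")
def noiseless_oce_config():
    return synth.OCESimConfig(true_speed_mps=2.0, phase_noise_std_rad=0.0)


@pytest.fixture(scope="session")
def calibration():
    """Three-material calibration recovered from noiseless synthetic spectra."""
    materials = synth.default_calibration_shifts()
    spectra = synth.make_calibration_set(materials, synth.BrillouinSimConfig())
    return brillouin.calibrate([(s, s.metadata["known_shift_ghz"]) for s in spectra])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
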