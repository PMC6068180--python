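import numpy as np
import pytest

from spdeconv.noise import NoiseParams
from spdeconv.psf import OpticalParams
from spdeconv.phantoms import SIMULATION_OPTICS, simulated_psf_cached


@pytest.fixture(scope="session")
def study_optics() -> OpticalParams:
    """Optical settings of the simulation study (high-NA oil objective)."""
    return SIMULATION_OPTICS


@pytest.fixture(scope="session")
def study_noise() -> NoiseParams:
    return NoiseParams(gain=2.0, read_sigma=3.0)


@pytest.fixture(scope="session")
def small_psf(study_optics):
    """Shared 9x64x64 simulated PSF (session-cached; simulation is the slow part)."""
    return simulated_psf_cached(study_optics, (9, 64, 64))


@pytest.fixture(scope="session")
def tiny_psf(study_optics):
    """Shared 9x32x32 simulated PSF for solver-scale tests."""
    return simulated_psf_cached(study_optics, (9, 32, 32))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
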