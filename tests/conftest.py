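import numpy as np
import pytest
from hypothesis import settings

from serstdm import synthgen as gen

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic calibration design: 6 levels x 5 replicates, 696 channels."""
    return gen.generate_calibration_dataset(seed=1)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, homogeneous generator for exact-arithmetic checks."""
    return gen.GeneratorConfig(noise_sd=0.0, pixel_heterogeneity=0.0)


def lorentzian(axis, center, fwhm):
    hw = fwhm / 2.0
    return hw**2 / ((axis - center) ** 2 + hw**2)


def expected_clean_spectrum(config, concentration, enhancement=1.0):
    """Independent closed-form expectation of a noise-free spectrum."""
    axis = config.wavenumber_axis
    cleanup = config.cleanup_effects[config.cleanup_method]
    analyte = np.zeros_like(axis)
    for band in config.analyte_bands:
        assert band.shape == "lorentzian"
        analyte += band.response * lorentzian(axis, band.center, band.width)
    interf = np.zeros_like(axis)
    for band in config.interferent_bands:
        interf += band.response * lorentzian(axis, band.center, band.width)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = sum(
        c * u**k for k, c in enumerate(config.baseline_coefficients)
    )
    return baseline + enhancement * (
        cleanup.analyte_recovery * analyte * concentration
        + cleanup.interferent_scale * interf
    )
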