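import numpy as np
import pytest
from hypothesis import settings

from specbind.spectra import Spectrum, SpectrumKind
from specbind.synthetic import SyntheticConfig

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Default study conditions with the noise turned off."""
    return SyntheticConfig(noise_sd=0.0)


@pytest.fixture
def single_site_config() -> SyntheticConfig:
    """One site class matching the low-concentration window ground truth."""
    return SyntheticConfig(sites=((3.1419e4, 0.6402),), noise_sd=0.0)


def gaussian_spectrum(center=340.0, sigma=12.0, amplitude=1.0, lo=280.0, hi=420.0,
                      step=1.0, kind=SpectrumKind.FLUORESCENCE) -> Spectrum:
    wl = np.arange(lo, hi + step / 2, step)
    return Spectrum(wl, amplitude * np.exp(-((wl - center) ** 2) / (2 * sigma**2)), kind)
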