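import numpy as np
import pytest

from scraman import default_axis, preset_profiles
from scraman.spectra_io import Spectrum


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def presets():
    return {p.name: p for p in preset_profiles()}


@pytest.fixture
def make_spectrum(axis):
    def _make(intensities=None, fn=None, **kwargs):
        if intensities is None:
            intensities = fn(axis.shifts) if fn else np.zeros(axis.n_pixels)
        return Spectrum(axis, np.asarray(intensities, dtype=float), **kwargs)

    return _make
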