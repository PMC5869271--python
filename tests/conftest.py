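import numpy as np
import pytest

from anthoquant import CameraModel, PigmentModel, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(20180216)


@pytest.fixture
def pigment_model():
    return PigmentModel()


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def flat_spectrum():
    """Factory for flat spectra on a 1-nm 300–800 grid."""

    def make(level: float = 1.0) -> Spectrum:
        wl = np.arange(300.0, 801.0, 1.0)
        return Spectrum(wl, np.full_like(wl, level))

    return make


@pytest.fixture
def piecewise_spectrum():
    """Factory: spectrum taking constant values over given (lo, hi) windows,
    with a fill value elsewhere, on a 1-nm 300–800 grid."""

    def make(windows, fill: float = 1.0) -> Spectrum:
        wl = np.arange(300.0, 801.0, 1.0)
        r = np.full_like(wl, fill)
        for (lo, hi), value in windows:
            r[(wl >= lo) & (wl <= hi)] = value
        return Spectrum(wl, r)

    return make
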