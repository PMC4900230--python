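import numpy as np
import pytest

from carbscreen import Band, BandShape, spectrum_from_bands


@pytest.fixture
def two_band_spectrum():
    """Noiseless D1 + G spectrum with a well-defined height ratio of 1.4."""
    bands = [
        Band("D1", BandShape.LORENTZIAN, 1350.0, 1.4, 80.0),
        Band("G", BandShape.LORENTZIAN, 1580.0, 1.0, 60.0),
    ]
    return spectrum_from_bands(bands, noise_sd=0.0), bands


@pytest.fixture
def grid():
    return np.arange(1000.0, 1801.0, 1.0)
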