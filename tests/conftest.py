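import pytest

import flagellabeat as fb


@pytest.fixture
def calib() -> fb.CalibrationConstants:
    return fb.default_calibration()


@pytest.fixture
def scheme() -> fb.BandScheme:
    return fb.make_band_scheme(0.0, 30.0, 3.0)
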