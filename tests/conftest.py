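import numpy as np
import pytest

from smstoich import Affine2D, LabelingParams


@pytest.fixture
def rng():
    return np.random.default_rng(20160928)


@pytest.fixture
def u2af35_labeling():
    """mCherry-U2AF35 calibration: 75% labeled, free spots 189:33 (1:2 steps)."""
    return LabelingParams(f_labeled=0.75, dimer_1step=189, dimer_2step=33)


@pytest.fixture
def u2af65_labeling():
    """mEGFP-U2AF65 calibration: 69% labeled, free spots 243:33."""
    return LabelingParams(f_labeled=0.69, dimer_1step=243, dimer_2step=33)


@pytest.fixture
def small_chromatic():
    """A realistic small chromatic distortion: ~1 px shift, 0.2% scale."""
    return Affine2D(((1.002, 0.0005), (-0.0004, 0.998)), (1.2, -0.8))
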