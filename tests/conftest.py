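import numpy as np
import pytest

from clubkit import FingerProfileSpec, render_finger_profile, segment_finger


@pytest.fixture(scope="session")
def mild_sample():
    """One default render with a clearly visible fold (165 deg, 5 cm)."""
    return render_finger_profile(FingerProfileSpec(lovibond_angle_deg=165.0, seed=3))


@pytest.fixture(scope="session")
def mild_mask(mild_sample):
    return segment_finger(mild_sample.image)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
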