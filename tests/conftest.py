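import numpy as np
import pytest

from mammoband.phantom import (
    DefectSpec,
    PhantomSpec,
    generate_phantom,
    generate_phantom_with_truth,
    inject_band_defect,
)


@pytest.fixture(scope="session")
def phantom_and_truth():
    """One 512x512 defect-free phantom with ground truth."""
    return generate_phantom_with_truth(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def phantom(phantom_and_truth):
    return phantom_and_truth[0]


@pytest.fixture(scope="session")
def defected_phantom():
    """Phantom with a saturating band defect plus its ground truth spec."""
    img = generate_phantom(PhantomSpec(seed=11))
    spec = DefectSpec(center_col=180, width=15, gain_profile=255.0,
                      loss_profile=30.0, ramp_gain=60.0)
    out, truth = inject_band_defect(img, spec)
    return out, truth


@pytest.fixture
def toy_image():
    """10x10 flat field of 128 with a 3-column saturated stripe."""
    img = np.full((10, 10), 128, np.uint8)
    img[:, 4:7] = 255
    return img
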