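import numpy as np
import pytest
from hypothesis import settings

from vishsi import calibration as cal
from vishsi import colorimetry as col
from vishsi import synthetic_data as syn

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


def camera_xyz_from_checker(checker):
    """Camera-side XYZ of a checker set: gamma decode then sRGB→XYZ."""
    return col.linear_rgb_to_xyz(col.gamma_decode(checker.camera_rgb))


@pytest.fixture(scope="session")
def noiseless_calibration():
    """Noiseless synthetic checker with its fitted conversion model."""
    checker, illuminant = syn.make_color_checker(seed=7)
    cam_xyz = camera_xyz_from_checker(checker)
    model = cal.fit_conversion_model(checker, cam_xyz, illuminant=illuminant)
    return {
        "checker": checker,
        "illuminant": illuminant,
        "camera_xyz": cam_xyz,
        "model": model,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
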