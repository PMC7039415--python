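import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from anisosim.blockmatch_registration import Image3D
from anisosim.synthetic_fixtures import default_brain_spec, make_phantom
from anisosim.transform_core import ScalingFrame


def random_rotation(seed: int) -> np.ndarray:
    R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1
    return R


def random_frame(seed: int) -> ScalingFrame:
    return ScalingFrame(random_rotation(seed))


@pytest.fixture(scope="session")
def brain_spec():
    """Mid-size textured brain phantom spec used by the registration tests."""
    return dataclasses.replace(
        default_brain_spec(noise_sigma=0.5, seed=7),
        shape=(48, 48, 48),
        spacing=(2.5, 2.5, 2.5),
    )


@pytest.fixture(scope="session")
def brain_phantom(brain_spec):
    img, masks = make_phantom(brain_spec)
    return img, masks


@pytest.fixture(scope="session")
def masked_brain(brain_phantom):
    img, masks = brain_phantom
    return Image3D(img.data, img.affine, mask=masks["brain"])


@pytest.fixture(scope="session")
def brain_spec64():
    """Full-resolution phantom spec (64³, 2 mm) for recovery-accuracy tests."""
    return default_brain_spec(noise_sigma=0.5, seed=7)


@pytest.fixture(scope="session")
def brain_phantom64(brain_spec64):
    return make_phantom(brain_spec64)


@pytest.fixture(scope="session")
def masked_brain64(brain_phantom64):
    img, masks = brain_phantom64
    return Image3D(img.data, img.affine, mask=masks["brain"])
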