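import numpy as np
import pytest

from psmatlp import (
    LabelMask,
    MaskRole,
    SegmentationConfig,
    SuvImage,
    default_phantom_spec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom: liver + two excluded organs + three lesions."""
    return generate_phantom(default_phantom_spec(seed=42))


@pytest.fixture
def sphere_image():
    """SUV-1 background with one uniform SUV-8 ball of radius 8 mm at
    spacing (2,2,2): exactly the 257 lattice points within 4 voxels."""
    shape = (16, 16, 16)
    vox = np.full(shape, 1.0)
    center = np.array([8, 8, 8])
    grids = np.indices(shape)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    vox[dist2 <= 16] = 8.0
    return SuvImage(voxels=vox, spacing=(2.0, 2.0, 2.0), patient_id="sphere")


def make_mask(shape, role=MaskRole.EXCLUSION, spacing=(1.0, 1.0, 1.0), ones=False):
    arr = np.ones(shape, dtype=np.int16) if ones else np.zeros(shape, dtype=np.int16)
    return LabelMask(voxels=arr, role=role, spacing=spacing)


@pytest.fixture
def make_label_mask():
    return make_mask
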