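import numpy as np
import pytest

from octaquant.binarize import compute_vld_threshold
from octaquant.image_io import EnFaceImage, Plexus
from octaquant.synthetic import SyntheticSpec, generate_angiogram

#: Disjoint-support spec used by several end-to-end tests: noise pixels can
#: reach at most 55, vessel pixels start at 150.
DISJOINT_SPEC = SyntheticSpec(
    noise_intensity=(20, 55), vessel_intensity=(150, 230), rng_seed=0
)


@pytest.fixture(scope="session")
def synthetic_eye():
    """One full-size synthetic eye (all four slabs) with ground truth."""
    return generate_angiogram(DISJOINT_SPEC)


@pytest.fixture(scope="session")
def eye_threshold(synthetic_eye):
    """Threshold derivation for the shared synthetic eye (expensive)."""
    images, _ = synthetic_eye
    return compute_vld_threshold(images[Plexus.DCP])


def make_image(pixels, plexus=Plexus.DCP, fov_mm=3.0, bit_depth=8):
    return EnFaceImage(
        pixels=np.asarray(pixels), plexus=plexus, fov_mm=fov_mm, bit_depth=bit_depth
    )
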