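import numpy as np
import pytest

from granuloscope.phantoms import (
    GranulePhantomConfig,
    VesiclePhantomConfig,
    make_granule_phantom,
    make_vesicle_phantom,
)


@pytest.fixture(scope="session")
def granule_truth():
    """Small native-style granule phantom shared across read-only tests."""
    cfg = GranulePhantomConfig(shape_voxels=(48, 96, 96), seed=1234)
    return make_granule_phantom(cfg)


@pytest.fixture(scope="session")
def vesicle_truth():
    """Small packed-vesicle phantom with quiet background texture."""
    cfg = VesiclePhantomConfig(
        n_vesicles=6,
        vesicle_radius_nm=250.0,
        shape_voxels=(48, 160, 160),
        background_texture_std=0.02,
        seed=3,
    )
    return make_vesicle_phantom(cfg)


def dice(mask: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(mask, truth).sum()
    return 2.0 * inter / (mask.sum() + truth.sum())
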