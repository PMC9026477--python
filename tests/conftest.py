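import numpy as np
import pytest

from softlabeler.superpixel import SlicParams
from softlabeler.synthetic import SynthConfig, generate_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def disk_mask_32():
    """32x32 mask with a centered radius-10 disk."""
    rr, cc = np.mgrid[0:32, 0:32]
    return (np.hypot(rr - 15.5, cc - 15.5) <= 10).astype(np.uint8)


@pytest.fixture(scope="session")
def small_fixture():
    """One 96x96 synthetic image/mask pair used across modules."""
    cfg = SynthConfig(height=96, width=96, lesion_area_range=(0.08, 0.3),
                      texture_scale=4.0, seed=11)
    return generate_pair(cfg)


@pytest.fixture(scope="session")
def small_params():
    return SlicParams(n_segments=64)


def random_blob_mask(shape, rng, p_lesion=0.35):
    """Random binary mask guaranteed to contain both classes (smoothed
    noise thresholded), for brute-force oracle comparisons."""
    from scipy import ndimage
    while True:
        field = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        mask = (field > np.quantile(field, 1 - p_lesion)).astype(np.uint8)
        if 0 < mask.sum() < mask.size:
            return mask
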