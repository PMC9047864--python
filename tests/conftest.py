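from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from radrepro import ImageVolume, RoiMask

UNIT = (1.0, 1.0, 1.0)
CT = (0.97, 0.97, 3.0)


def volume(array, spacing=UNIT, origin=(0.0, 0.0, 0.0)) -> ImageVolume:
    return ImageVolume(np.asarray(array, dtype=float), spacing, origin)


def roi(array, spacing=UNIT, origin=(0.0, 0.0, 0.0)) -> RoiMask:
    return RoiMask(np.asarray(array, dtype=np.uint8), spacing, origin)


def random_phantom(rng: np.random.Generator, shape=(16, 16, 16), spacing=UNIT):
    """Small random textured image with a random connected blob mask."""
    img = 40.0 + 60.0 * ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    mask = field > np.percentile(field, 70)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n == 0:  # pragma: no cover - extremely unlikely
        mask[tuple(s // 2 for s in shape)] = True
    else:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == int(np.argmax(sizes)) + 1
    return volume(img, spacing), roi(mask, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
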