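import numpy as np
import pytest
from scipy import ndimage
from skimage import draw
from skimage.morphology import disk, opening

from sonodice import PhantomConfig, SectorGeometry


@pytest.fixture
def small_config():
    """Desk-scale phantom: 128×96 rasters, full default error model."""
    return PhantomConfig(image_width=128, image_height=96)


@pytest.fixture
def blob_factory():
    """Random simply-connected blobs fully inside the default sector.

    Built from overlapping disks, opened with a radius-2 disk so every part
    is at least ~2 px thick (the regime in which boundary-extraction →
    fill round-trips are exact), largest component kept, holes filled.
    Grid is 64×96; disk centers are confined to a box that keeps every blob
    pixel strictly inside the sector scan area.
    """

    shape = (64, 96)

    def make(rng: np.random.Generator) -> np.ndarray:
        while True:
            mask = np.zeros(shape, dtype=bool)
            for _ in range(rng.integers(3, 7)):
                r = rng.integers(24, 35)
                c = rng.integers(40, 57)
                rad = rng.integers(5, 9)
                rr, cc = draw.disk((r, c), rad, shape=shape)
                mask[rr, cc] = True
            mask = opening(mask, disk(2)).astype(bool)
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
            if n == 0:
                continue
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (int(np.argmax(sizes)) + 1)
            mask = ndimage.binary_fill_holes(mask)
            if mask.sum() >= 50:
                return mask

    return make


@pytest.fixture
def blob_sector():
    return SectorGeometry((64, 96))
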