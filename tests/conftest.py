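import numpy as np
import pytest

from nemasex import datasets, synth
from nemasex.classifier import fit_training
from nemasex.segmentation import WormRegion


def region_from_mask(mask, um_per_pixel=6.5, region_id=0):
    """Wrap a raw boolean mask as a WormRegion at its own bounding box."""
    mask = np.asarray(mask, dtype=bool)
    return WormRegion(
        mask=mask,
        bbox=(0, 0, *mask.shape),
        area_px=int(mask.sum()),
        touches_border=False,
        um_per_pixel=um_per_pixel,
        region_id=region_id,
    )


def rectangle_region(length_px, width_px, um_per_pixel=6.5, pad=4):
    m = np.zeros((width_px + 2 * pad, length_px + 2 * pad), dtype=bool)
    m[pad : pad + width_px, pad : pad + length_px] = True
    return region_from_mask(m, um_per_pixel)


@pytest.fixture(scope="session")
def shipped_records():
    return datasets.training_records()


@pytest.fixture(scope="session")
def shipped_model(shipped_records):
    return fit_training(shipped_records)


@pytest.fixture(scope="session")
def worm_pool():
    """Measured features for a labelled pool of rendered worms (split experiments)."""
    return synth.generate_training_records(
        {"hermaphrodite": 60, "male": 60, "larva": 50}, seed=1234
    )
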