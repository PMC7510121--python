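import numpy as np
import pytest

from beadquant.core_io import FluorescenceImage, ImageMeta, InstanceMask, SegmentationResult


def rect_mask(shape, r0, r1, c0, c1, score=1.0, label_id=1):
    """Axis-aligned rectangle instance, rows r0..r1-1, cols c0..c1-1."""
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return InstanceMask(m, score=score, label_id=label_id)


def overlap31_candidate(shape, score=0.9, label_id=3):
    """Area-100 mask overlapping rows 0-9 x cols 0-9 by exactly 31 px:
    the 10x10 rect at rows 7-16 (30 px overlap) with one pixel moved from
    (16, 9) to (6, 0) inside the kept square."""
    m = np.zeros(shape, dtype=bool)
    m[7:17, 0:10] = True
    m[16, 9] = False
    m[6, 0] = True
    return InstanceMask(m, score=score, label_id=label_id)


def disc_mask(shape, center, radius, score=1.0, label_id=1):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return InstanceMask(m, score=score, label_id=label_id)


@pytest.fixture
def two_bead_fixture():
    """Worked fixture: two rectangular beads of areas 50 and 150 px on a
    constant-intensity-100 image, centroid distance exactly 5 px.

    Bead A: 5 x 10 rect, rows 20-24, cols 30-39  -> centroid (22, 34.5)
    Bead B: 15 x 10 rect, rows 18-32, cols 34-43 -> centroid (25, 38.5)
    distance = hypot(3, 4) = 5.
    """
    shape = (64, 64)
    img = FluorescenceImage(np.full(shape, 100, dtype=np.uint16), ImageMeta())
    a = rect_mask(shape, 20, 25, 30, 40, label_id=1)
    b = rect_mask(shape, 18, 33, 34, 44, label_id=2)
    seg = SegmentationResult([a, b], shape, backend_name="fixture")
    return img, seg


@pytest.fixture(scope="session")
def young_scene():
    """One deterministic rendered young-profile scene (session-cached)."""
    from beadquant import synthetic as syn

    return syn.generate_scene(syn.DEFAULT_PROFILES["young"], shape=(512, 512), seed=11)
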