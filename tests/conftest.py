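import numpy as np
import pytest

from stemscan.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def pixel_cells(box: Box) -> set[tuple[int, int]]:
    """Integer pixel cells covered by a box with integer corners."""
    return {
        (x, y)
        for x in range(int(box.xmin), int(box.xmax))
        for y in range(int(box.ymin), int(box.ymax))
    }


def brute_force_iou(a: Box, b: Box) -> float:
    """Pixel-counting IOU oracle for integer-corner boxes."""
    ca, cb = pixel_cells(a), pixel_cells(b)
    return len(ca & cb) / len(ca | cb)


def brute_force_overlap_fraction(a: Box, b: Box) -> float:
    ca, cb = pixel_cells(a), pixel_cells(b)
    return len(ca & cb) / min(len(ca), len(cb))


def random_int_box(rng, span: int = 40, max_side: int = 15) -> Box:
    x = int(rng.integers(0, span))
    y = int(rng.integers(0, span))
    w = int(rng.integers(1, max_side))
    h = int(rng.integers(1, max_side))
    return Box(x, y, x + w, y + h)
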