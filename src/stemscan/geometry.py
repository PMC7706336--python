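"""Axis-aligned box arithmetic and detection post-processing.

Boxes use 0-based, half-open pixel coordinates ``[xmin, xmax) x [ymin, ymax)``
with x rightward and y downward (origin at the top-left corner of the image).
Detection post-processing follows the standard high-resolution imaging recipe:
tile large images into fixed-size patches with 50 % overlap, run a detector on
each patch, translate candidates back to parent coordinates, eliminate
cross-patch duplicates at a 0.75 overlap fraction, and discard candidates with
a confidence score below 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

__all__ = [
    "Box",
    "Detection",
    "TilingPlan",
    "iou",
    "overlap_fraction",
    "plan_tiling",
    "merge_across_patches",
    "filter_by_score",
]


@dataclass(frozen=True, order=True)
class Box:
    """Axis-aligned rectangle in half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def clip(self, width: float, height: float) -> "Box":
        """Clip to an image extent ``[0, width) x [0, height)``."""
        return Box(
            max(self.xmin, 0.0),
            max(self.ymin, 0.0),
            min(self.xmax, width),
            min(self.ymax, height),
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class Detection:
    """A candidate stem bounding box with a confidence score in [0, 1].

    ``patch_offset`` records the anchor of the source patch in the parent
    image; the box itself is always stored in parent-image coordinates.
    """

    box: Box
    score: float
    patch_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"confidence score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class TilingPlan:
    """Row-major patch anchors covering an image."""

    patch_size: int
    stride: int
    offsets: tuple[tuple[int, int], ...]
    image_size: tuple[int, int] = (0, 0)  # (width, height)

    def patches(self):
        """Yield (x, y, w, h) with the patch clipped to the image."""
        width, height = self.image_size
        for x, y in self.offsets:
            yield x, y, min(self.patch_size, width - x), min(self.patch_size, height - y)


def _intersection_area(a: Box, b: Box) -> float:
    w = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    h = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes. Symmetric, in [0, 1]."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def overlap_fraction(a: Box, b: Box) -> float:
    """Intersection area over the smaller of the two box areas.

    This is the duplicate-elimination measure: a box nested inside another
    scores 1.0 regardless of the size difference, which is exactly the
    situation cross-patch duplication creates.
    """
    inter = _intersection_area(a, b)
    return inter / min(a.area, b.area)


def plan_tiling(
    width: int, height: int, patch_size: int = 1000, overlap: float = 0.5
) -> TilingPlan:
    """Plan fixed-size patch anchors with the given fractional overlap.

    Anchors advance by ``stride = patch_size * (1 - overlap)``; when the last
    regular anchor does not reach the image edge a final anchor is clamped to
    ``dim - patch_size``. Images smaller than the patch yield a single anchor
    at 0 with the patch clipped to the image (no padding, so no synthetic
    border content is created).
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap {overlap} outside [0, 1)")
    stride = max(1, int(round(patch_size * (1.0 - overlap))))

    def axis_anchors(dim: int) -> list[int]:
        if dim <= patch_size:
            return [0]
        anchors = list(range(0, dim - patch_size + 1, stride))
        if anchors[-1] + patch_size < dim:
            anchors.append(dim - patch_size)
        return anchors

    xs = axis_anchors(width)
    ys = axis_anchors(height)
    offsets = tuple((x, y) for y in ys for x in xs)
    return TilingPlan(patch_size=patch_size, stride=stride, offsets=offsets,
                      image_size=(width, height))


def _sort_key(d: Detection):
    # Score descending, then position-lexicographic for deterministic ties.
    return (-d.score, d.box.as_tuple())


def greedy_suppress(
    dets: Sequence[Detection],
    measure: Callable[[Box, Box], float],
    threshold: float,
) -> list[Detection]:
    """Greedy suppression in score-descending order under an overlap measure.

    A detection is kept iff its overlap with every already-kept detection is
    below ``threshold``; ties in score are broken position-lexicographically,
    so the result is deterministic and idempotent.
    """
    kept: list[Detection] = []
    for d in sorted(dets, key=_sort_key):
        if all(measure(d.box, k.box) < threshold for k in kept):
            kept.append(d)
    return kept


def merge_across_patches(
    dets: Sequence[Detection], overlap_threshold: float = 0.75
) -> list[Detection]:
    """Eliminate cross-patch duplicates at a minimum overlap fraction.

    Detections must already be in parent-image coordinates. Within each
    conflicting pair the lower-score member is removed (higher score wins).
    """
    return greedy_suppress(dets, overlap_fraction, overlap_threshold)


def filter_by_score(dets: Sequence[Detection], threshold: float = 0.80) -> list[Detection]:
    """Keep detections with score >= threshold, preserving order.

    The cut is inclusive: only candidates with a score strictly smaller than
    the threshold are discarded.
    """
    return [d for d in dets if d.score >= threshold]
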