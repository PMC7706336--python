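"""Stem-candidate detection.

Two sources of candidates are supported behind the same contract
("boxes + scores in, traits out"):

* external detections produced by any detector (e.g. a fine-tuned deep
  network run elsewhere), ingested from CSV/JSON; and
* a built-in classical ring detector: zero-mean normalized cross-correlation
  (ZNCC) against annulus templates spanning a radius range, suitable for the
  bright-ring-on-darker-surround appearance of cut stems. Stems are located
  by relative pixel brightness, so color carries no extra information here.

Either way, candidates flow through the same post-processing: tiling,
translation to parent coordinates, cross-patch duplicate elimination at 0.75
overlap fraction and the 0.80 confidence cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, peak_local_max

from .geometry import (
    Box,
    Detection,
    filter_by_score,
    greedy_suppress,
    iou,
    merge_across_patches,
    plan_tiling,
)

__all__ = ["DetectorConfig", "detect_rings", "run_detection_pipeline"]

#: Box half-side margin beyond the detected ring radius, as a fraction of the
#: radius, so diameter profiles capture background on both sides.
BOX_MARGIN_FRACTION = 0.25


@dataclass(frozen=True)
class DetectorConfig:
    """Ring-detector settings.

    radius_min/radius_max bound the ring-center radii searched, in pixels;
    they should bracket (expected diameter in mm / resolution) / 2. The
    correlation peak is mapped to a confidence score via (corr + 1) / 2;
    ``score_floor`` discards weak candidates early. Non-maximum suppression
    removes same-scale duplicates at IOU >= ``nms_iou``.
    """

    radius_min: float
    radius_max: float
    score_floor: float = 0.60
    nms_iou: float = 0.2
    ring_sigma: float = 1.2  # radial width of the template annulus, px
    n_radii: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.radius_min <= self.radius_max:
            raise ValueError("need 0 < radius_min <= radius_max")
        if not 0.0 <= self.score_floor <= 1.0:
            raise ValueError("score_floor outside [0, 1]")

    @classmethod
    def for_resolution(
        cls, resolution_mm_per_px: float, mean_diameter_mm: float = 2.1, **kw
    ) -> "DetectorConfig":
        """Radius range bracketing a diameter distribution at a resolution."""
        r = mean_diameter_mm / resolution_mm_per_px / 2.0
        return cls(radius_min=max(2.0, 0.45 * r), radius_max=2.0 * r, **kw)


def _annulus_template(radius: float, sigma: float) -> np.ndarray:
    """Gaussian-profiled bright ring template, background at 0."""
    m = int(np.ceil(radius + 3.0 * sigma))
    yy, xx = np.mgrid[-m : m + 1, -m : m + 1].astype(float)
    rr = np.hypot(xx, yy)
    return np.exp(-((rr - radius) ** 2) / (2.0 * sigma**2))


def detect_rings(gray: np.ndarray, cfg: DetectorConfig) -> list[Detection]:
    """Find ring-shaped stems in a single-channel image.

    ZNCC response maps are computed for templates at ``n_radii`` radii
    spanning [radius_min, radius_max]; the per-pixel maximum over radii is
    searched for local peaks, each peak becomes a square box of side
    2 * radius * (1 + margin) centered on it, and candidates are thinned by
    non-maximum suppression at IOU >= cfg.nms_iou (higher score wins).

    The response is invariant to gain/offset changes of the image (ZNCC is
    mean- and variance-normalized), so a uniform background offset does not
    change the detections.
    """
    gray = np.asarray(gray, dtype=float)
    h, w = gray.shape
    if 2.0 * cfg.radius_max > min(h, w) / 2.0:
        raise ValueError("radius range wider than half the image")
    radii = np.linspace(cfg.radius_min, cfg.radius_max, cfg.n_radii)
    best_corr = np.full((h, w), -1.0)
    best_radius = np.full((h, w), radii[0])
    for r in radii:
        tmpl = _annulus_template(r, cfg.ring_sigma)
        corr = match_template(gray, tmpl, pad_input=True, mode="reflect")
        take = corr > best_corr
        best_corr[take] = corr[take]
        best_radius[take] = r
    corr_floor = 2.0 * cfg.score_floor - 1.0
    peaks = peak_local_max(
        best_corr,
        min_distance=max(1, int(cfg.radius_min)),
        threshold_abs=corr_floor,
        exclude_border=False,
    )
    candidates = []
    for i, j in peaks:
        r = best_radius[i, j]
        half = r * (1.0 + BOX_MARGIN_FRACTION)
        # Peak pixel (i, j) has continuous center (j + 0.5, i + 0.5).
        cx, cy = j + 0.5, i + 0.5
        box = Box(cx - half, cy - half, cx + half, cy + half).clip(w, h)
        score = float((best_corr[i, j] + 1.0) / 2.0)
        candidates.append(Detection(box=box, score=min(score, 1.0)))
    return greedy_suppress(candidates, iou, cfg.nms_iou)


def run_detection_pipeline(
    image: np.ndarray,
    cfg: DetectorConfig | None = None,
    detections: list[Detection] | None = None,
    patch_size: int = 1000,
    overlap: float = 0.5,
    merge_overlap: float = 0.75,
    score_threshold: float = 0.80,
    merge_before_filter: bool = True,
) -> list[Detection]:
    """Full detection post-processing for one image.

    Either run the ring detector per tile of the image (``cfg`` given) or take
    externally produced ``detections`` already in parent coordinates. In both
    cases candidates are merged across patches at ``merge_overlap`` fraction
    and cut at ``score_threshold``; by default duplicates are merged before
    the score cut (the order is configurable via ``merge_before_filter``).
    Deterministic for fixed inputs.
    """
    from .diameter import gray_image

    if (cfg is None) == (detections is None):
        raise ValueError("provide exactly one of cfg (detector) or detections (file)")
    if cfg is not None:
        gray = gray_image(image)
        h, w = gray.shape
        plan = plan_tiling(w, h, patch_size=patch_size, overlap=overlap)
        pooled: list[Detection] = []
        for x, y, pw, ph in plan.patches():
            tile = gray[y : y + ph, x : x + pw]
            for d in detect_rings(tile, cfg):
                pooled.append(
                    Detection(
                        box=d.box.translate(x, y).clip(w, h),
                        score=d.score,
                        patch_offset=(float(x), float(y)),
                    )
                )
    else:
        pooled = list(detections)
    if merge_before_filter:
        return filter_by_score(merge_across_patches(pooled, merge_overlap), score_threshold)
    return merge_across_patches(filter_by_score(pooled, score_threshold), merge_overlap)
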