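"""Stem diameter from gray-value profiles.

A cut stem viewed from above appears as a bright ring (the stem wall) around
a darker lumen, on a darker background. Gray-value profiles through the box
center along the four compass directions 0°, 45°, 90° and 135° are therefore
bimodal: one intensity maximum per stem border. The distance between the two
maxima, averaged over the directions, estimates the diameter of the circle
running through the middle of the stem wall (the ring-center diameter).

Gray conversion uses the fixed linear combination
``V = 0.2989 R + 0.5870 G + 0.1140 B`` of the 8-bit channels, without
rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .geometry import Box, Detection

__all__ = [
    "GRAY_WEIGHTS",
    "PROFILE_DIRECTIONS_DEG",
    "GrayPatch",
    "Profile",
    "ProfileSet",
    "StemMeasurement",
    "to_gray",
    "gray_image",
    "gray_patch_from_image",
    "extract_profiles",
    "diameter_from_profile",
    "measure_stem",
    "measure_stems",
]

#: Luma weights applied to the R, G, B channels.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Compass directions of the gray-value profiles, degrees from the x axis.
PROFILE_DIRECTIONS_DEG = (0.0, 45.0, 90.0, 135.0)

#: Spacing of profile samples along the line, in pixels.
PROFILE_STEP_PX = 0.5


@dataclass(frozen=True)
class GrayPatch:
    """A single-channel crop with its offset in the parent image."""

    values: np.ndarray  # 2-D float array, gray levels in [0, 255]
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) parent-image offset


@dataclass(frozen=True)
class Profile:
    """Gray values sampled along one direction through the box center.

    Positions are signed distances (pixels) from the center along the line.
    """

    angle_deg: float
    positions: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class ProfileSet:
    profiles: tuple[Profile, ...]
    center: tuple[float, float]  # parent-image coordinates


@dataclass(frozen=True)
class StemMeasurement:
    detection: Detection
    per_direction_px: tuple[float | None, ...]
    mean_diameter_px: float | None
    diameter_mm: float | None
    valid: bool


def to_gray(r, g, b):
    """Convert 8-bit R, G, B values to an unrounded gray level.

    Accepts scalars or arrays; raises if any channel lies outside [0, 255].
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, c in (("R", r), ("G", g), ("B", b)):
        if np.any(c < 0) or np.any(c > 255):
            raise ValueError(f"{name} channel outside [0, 255]")
    v = GRAY_WEIGHTS[0] * r + GRAY_WEIGHTS[1] * g + GRAY_WEIGHTS[2] * b
    return float(v) if v.ndim == 0 else v


def gray_image(image: np.ndarray) -> np.ndarray:
    """Gray version of an (H, W) or (H, W, 3) uint8/float image."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return to_gray(arr[..., 0], arr[..., 1], arr[..., 2])
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {arr.shape}")


def gray_patch_from_image(image: np.ndarray, box: Box) -> GrayPatch:
    """Crop the (integer-expanded) box from an image as a GrayPatch."""
    gray = gray_image(image)
    h, w = gray.shape
    x0 = max(int(math.floor(box.xmin)), 0)
    y0 = max(int(math.floor(box.ymin)), 0)
    x1 = min(int(math.ceil(box.xmax)), w)
    y1 = min(int(math.ceil(box.ymax)), h)
    return GrayPatch(values=gray[y0:y1, x0:x1], origin=(float(x0), float(y0)))


def _sample_line(values: np.ndarray, center_xy: tuple[float, float],
                 angle_deg: float, half_length: float) -> Profile:
    """Bilinearly sample a profile through ``center_xy`` (patch coordinates).

    Continuous coordinates place the center of pixel cell (i, j) at
    (j + 0.5, i + 0.5); ``map_coordinates`` indexes pixel centers directly,
    hence the 0.5 shift below.
    """
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    n = int(math.floor(half_length / PROFILE_STEP_PX))
    t = np.arange(-n, n + 1) * PROFILE_STEP_PX
    xs = center_xy[0] + t * ux
    ys = center_xy[1] + t * uy
    vals = map_coordinates(values, np.vstack([ys - 0.5, xs - 0.5]),
                           order=1, mode="nearest")
    return Profile(angle_deg=angle_deg, positions=t, values=vals)


def extract_profiles(gray: GrayPatch, box: Box) -> ProfileSet:
    """Extract the four compass-direction profiles through the box center.

    Each profile is clipped to the box: samples run from the center out to the
    box boundary along both senses of the direction, at 0.5-px steps.
    """
    if box.width < 4 or box.height < 4:
        raise ValueError("box smaller than 4x4 px: profile too short")
    cx, cy = box.center
    # Patch-local continuous coordinates.
    lx, ly = cx - gray.origin[0], cy - gray.origin[1]
    profiles = []
    for angle in PROFILE_DIRECTIONS_DEG:
        theta = math.radians(angle)
        ux, uy = math.cos(theta), math.sin(theta)
        # Distance from center to the box boundary along +/-u (box is
        # center-symmetric about its own center).
        tx = (box.width / 2) / abs(ux) if abs(ux) > 1e-12 else math.inf
        ty = (box.height / 2) / abs(uy) if abs(uy) > 1e-12 else math.inf
        half = min(tx, ty)
        profiles.append(_sample_line(gray.values, (lx, ly), angle, half))
    return ProfileSet(profiles=tuple(profiles), center=(cx, cy))


def _refine_peak(positions: np.ndarray, values: np.ndarray, idx: int) -> float:
    """Parabolic sub-sample refinement over the 3 samples around a maximum."""
    if idx <= 0 or idx >= len(values) - 1:
        return float(positions[idx])
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:  # not a strict local maximum of the parabola
        return float(positions[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = positions[idx + 1] - positions[idx]
    return float(positions[idx] + delta * step)


def _side_peak(positions: np.ndarray, values: np.ndarray) -> float | None:
    """Position of the maximum on one side; None when unusable.

    Unusable sides: fewer than 5 samples, flat (no unique maximum), or the
    maximum sits at the outer endpoint (border truncated by the box edge).
    Ties are broken toward the center; positions must be ordered from the
    center outward.
    """
    if len(values) < 5:
        return None
    vmax = values.max()
    if vmax <= values.min():  # flat profile
        return None
    idx = int(np.flatnonzero(values == vmax)[0])  # nearest to center on ties
    if idx == len(values) - 1:  # outermost sample: truncated border
        return None
    # Map back to the original ordering for parabolic refinement.
    return _refine_peak(positions, values, idx)


def diameter_from_profile(profile: Profile, smooth_sigma: float = 0.0) -> float | None:
    """Distance in pixels between the intensity maxima of the two stem borders.

    Returns None (invalid) when either side of the center lacks a usable
    interior maximum. ``smooth_sigma`` optionally Gaussian-smooths the profile
    (in sample units) before the maxima are located; default is no smoothing.
    """
    pos = np.asarray(profile.positions, dtype=float)
    vals = np.asarray(profile.values, dtype=float)
    if smooth_sigma > 0:
        vals = gaussian_filter1d(vals, smooth_sigma, mode="nearest")
    left = pos < 0
    right = pos > 0
    # Order each side from the center outward so tie-breaking favors the center.
    p_left = _side_peak(pos[left][::-1], vals[left][::-1])
    p_right = _side_peak(pos[right], vals[right])
    if p_left is None or p_right is None:
        return None
    return float(p_right - p_left)


def measure_stem(
    gray: GrayPatch,
    det: Detection,
    resolution: float,
    smooth_sigma: float = 0.0,
    min_valid_directions: int = 2,
) -> StemMeasurement:
    """Measure one detected stem: per-direction distances and their mean.

    ``resolution`` is the ground sampling distance in mm/pixel. The
    measurement is valid when at least ``min_valid_directions`` directions
    yield a usable border-to-border distance and the mean lies inside the box
    diagonal.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0 (mm/pixel)")
    try:
        pset = extract_profiles(gray, det.box)
    except ValueError:
        return StemMeasurement(det, (None,) * 4, None, None, False)
    per_dir = tuple(diameter_from_profile(p, smooth_sigma) for p in pset.profiles)
    usable = [d for d in per_dir if d is not None and d > 0]
    diagonal = math.hypot(det.box.width, det.box.height)
    if len(usable) < min_valid_directions:
        return StemMeasurement(det, per_dir, None, None, False)
    mean_px = float(np.mean(usable))
    valid = 0.0 < mean_px < diagonal
    return StemMeasurement(det, per_dir, mean_px, mean_px * resolution, valid)


def measure_stems(
    image: np.ndarray,
    detections,
    resolution: float,
    smooth_sigma: float = 0.0,
) -> list[StemMeasurement]:
    """Measure every detection of an image. Convenience wrapper."""
    gray = gray_image(image)
    h, w = gray.shape
    out = []
    for det in detections:
        patch = gray_patch_from_image(gray, det.box.clip(w, h))
        out.append(measure_stem(patch, det, resolution, smooth_sigma))
    return out
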