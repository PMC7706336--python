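"""Synthetic stubble scenes and field trials with known ground truth.

The scene generator emulates nadir RGB images of a harvested wheat microplot:
cut stems appear as bright Gaussian-profiled annuli (the stem wall) around a
lumen slightly brighter than the soil background, placed along planting rows
0.17 m apart, with per-stem diameters drawn from a gamma law (defaults: shape
6, scale 0.35 mm, mean 2.1 mm) at a ground resolution of 0.12–0.18 mm/px.
Background clutter is modeled as Gaussian soil noise plus bright straw
streaks. Every stem's center, ring-center diameter and bounding box are
returned as ground truth, so detector and diameter code can be scored without
field data.

The trial generator emulates a replicated variety trial: per-genotype effects
drawn with variance Vg and per-plot residuals with variance Ve, so the
designed broad-sense heritability Vg/(Vg+Ve) is known, plus an above-ground
biomass column proportional to biovolume with multiplicative noise and an ear
density tracking stem density with a small discrepancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Box

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "TrialSpec",
    "render_scene",
    "render_annulus_patch",
    "generate_trial",
]

#: Ground-truth box half-side as a multiple of the ring radius; the margin
#: leaves background visible around the stem, as annotation guidance requires.
TRUTH_BOX_FACTOR = 1.25


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered microplot extract."""

    width: int = 1000
    height: int = 1000
    resolution: float = 0.18  # mm/px ground sampling distance
    row_spacing: float = 0.17  # m between planting rows
    density: float = 350.0  # stems/m²
    gamma_shape: float = 6.0
    gamma_scale: float = 0.35  # mm; mean diameter = shape*scale = 2.1 mm
    diameter_range: tuple[float, float] = (1.0, 4.0)  # mm, truncation bounds
    background: float = 70.0  # soil gray level
    lumen_contrast: float = 20.0  # lumen brightness above background
    ring_contrast: float = 130.0  # ring peak brightness above background
    blur_sigma: float = 1.2  # radial width of the ring profile, px
    noise_sigma: float = 8.0  # gray levels of additive background noise
    n_streaks: int = 2  # bright straw streaks
    occluded_fraction: float = 0.0
    seed: int = 0

    @property
    def area_m2(self) -> float:
        return (self.width * self.resolution / 1000.0) * (
            self.height * self.resolution / 1000.0
        )


@dataclass(frozen=True)
class SceneTruth:
    """Per-stem ground truth plus plot-level bookkeeping."""

    stems: pd.DataFrame  # cx, cy, radius_px, diameter_px, diameter_mm, occluded
    area_m2: float
    resolution: float

    @property
    def boxes(self) -> list[Box]:
        out = []
        for _, s in self.stems.iterrows():
            half = TRUTH_BOX_FACTOR * s.radius_px
            out.append(Box(s.cx - half, s.cy - half, s.cx + half, s.cy + half))
        return out


def _truncated_gamma(rng: np.random.Generator, shape: float, scale: float,
                     lo: float, hi: float, n: int) -> np.ndarray:
    """Gamma draws resampled into [lo, hi] (diameters below ~1 mm are not
    biologically plausible stems and would be invisible at these resolutions)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(shape, scale, size=2 * (n - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _place_stems(rng: np.random.Generator, spec: SceneSpec,
                 radii_px: np.ndarray) -> np.ndarray:
    """Place stem centers along rows with jitter and a minimum separation."""
    w, h = spec.width, spec.height
    spacing_px = spec.row_spacing * 1000.0 / spec.resolution
    n_rows = max(1, int(w // spacing_px))
    # Center the row pattern horizontally.
    row_x = (np.arange(n_rows) - (n_rows - 1) / 2.0) * spacing_px + w / 2.0
    min_sep = 2.2 * radii_px.max() + 2.0
    centers: list[tuple[float, float]] = []
    for r in radii_px:
        margin = TRUTH_BOX_FACTOR * r + 2.0
        placed = False
        for _ in range(400):
            rx = row_x[rng.integers(n_rows)]
            cx = rx + rng.normal(0.0, 3.0)
            cy = rng.uniform(margin, h - margin)
            cx = float(np.clip(cx, margin, w - margin))
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2
                   for px, py in centers):
                centers.append((cx, cy))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"packing failure: cannot place {len(radii_px)} stems at "
                f"density {spec.density}/m² in a {w}x{h} px scene"
            )
    return np.asarray(centers)


def _draw_ring(img: np.ndarray, cx: float, cy: float, radius: float,
               spec: SceneSpec) -> None:
    """Add one stem: bright annulus + slightly bright lumen, in place."""
    ext = int(math.ceil(radius + 4.0 * spec.blur_sigma))
    x0 = max(int(cx) - ext, 0)
    x1 = min(int(cx) + ext + 1, img.shape[1])
    y0 = max(int(cy) - ext, 0)
    y1 = min(int(cy) + ext + 1, img.shape[0])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
    ring = spec.ring_contrast * np.exp(-((rr - radius) ** 2) / (2.0 * spec.blur_sigma**2))
    lumen = spec.lumen_contrast * np.exp(-((rr / (0.55 * radius)) ** 4))
    img[y0:y1, x0:x1] += ring + lumen


def _draw_streak(img: np.ndarray, rng: np.random.Generator) -> None:
    """Add one bright straw streak: a soft-edged line segment."""
    h, w = img.shape
    p0 = rng.uniform([0, 0], [w, h])
    p1 = p0 + rng.uniform(-1, 1, 2) * rng.uniform(0.2, 0.6) * min(w, h)
    half_width = rng.uniform(1.0, 2.5)
    gain = rng.uniform(25.0, 55.0)
    x0 = int(np.clip(min(p0[0], p1[0]) - 4, 0, w))
    x1 = int(np.clip(max(p0[0], p1[0]) + 4, 0, w))
    y0 = int(np.clip(min(p0[1], p1[1]) - 4, 0, h))
    y1 = int(np.clip(max(p0[1], p1[1]) + 4, 0, h))
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.stack([xx + 0.5, yy + 0.5], axis=-1)
    seg = p1 - p0
    t = np.clip(((pts - p0) @ seg) / max(seg @ seg, 1e-9), 0.0, 1.0)
    proj = p0 + t[..., None] * seg
    dist = np.linalg.norm(pts - proj, axis=-1)
    img[y0:y1, x0:x1] += gain * np.exp(-((dist / half_width) ** 2))


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one annotated microplot extract. Deterministic per seed."""
    n_stems = int(round(spec.density * spec.area_m2))
    if n_stems < 1:
        raise ValueError("expected stem count < 1; enlarge the scene or density")
    rng = np.random.default_rng(spec.seed)
    diam_mm = _truncated_gamma(rng, spec.gamma_shape, spec.gamma_scale,
                               *spec.diameter_range, n_stems)
    radii_px = diam_mm / spec.resolution / 2.0
    centers = _place_stems(rng, spec, radii_px)

    img = np.full((spec.height, spec.width), spec.background, dtype=float)
    for (cx, cy), r in zip(centers, radii_px):
        _draw_ring(img, cx, cy, r, spec)
    occluded = np.zeros(n_stems, dtype=bool)
    if spec.occluded_fraction > 0:
        n_occ = int(round(spec.occluded_fraction * n_stems))
        idx = rng.choice(n_stems, size=n_occ, replace=False)
        occluded[idx] = True
        for i in idx:
            cx, cy = centers[i]
            r = radii_px[i]
            # A straw fragment lying across the ring.
            y0 = max(int(cy - 0.4 * r), 0)
            y1 = min(int(cy + 0.4 * r), spec.height)
            x0 = max(int(cx - 1.6 * r), 0)
            x1 = min(int(cx + 1.6 * r), spec.width)
            img[y0:y1, x0:x1] = spec.background + spec.ring_contrast * 0.9
    for _ in range(spec.n_streaks):
        _draw_streak(img, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 255.0)
    # Soil-toned RGB: constant per-channel gains keep intensity maxima in place.
    rgb = np.clip(
        np.stack([img * 1.0, img * 0.97, img * 0.90], axis=-1), 0, 255
    ).astype(np.uint8)

    stems = pd.DataFrame(
        {
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "radius_px": radii_px,
            "diameter_px": 2.0 * radii_px,
            "diameter_mm": diam_mm,
            "occluded": occluded,
        }
    )
    return rgb, SceneTruth(stems=stems, area_m2=spec.area_m2,
                           resolution=spec.resolution)


def render_annulus_patch(
    radius: float,
    center: tuple[float, float] | None = None,
    size: int | None = None,
    background: float = 70.0,
    lumen_contrast: float = 20.0,
    ring_contrast: float = 130.0,
    blur_sigma: float = 1.2,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a single stem cross-section as a gray patch.

    Returns the (size, size) float image and the continuous center used.
    The intensity maxima along any line through the center sit on the circle
    of the given radius (the ring-center circle), which is the ground truth
    the diameter estimator targets.
    """
    if size is None:
        size = int(math.ceil(2 * TRUTH_BOX_FACTOR * radius)) + 8
    if center is None:
        center = (size / 2.0, size / 2.0)
    cx, cy = center
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rr = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
    img = (
        background
        + ring_contrast * np.exp(-((rr - radius) ** 2) / (2.0 * blur_sigma**2))
        + lumen_contrast * np.exp(-((rr / (0.55 * radius)) ** 4))
    )
    if noise_sigma > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 255.0), (cx, cy)


@dataclass(frozen=True)
class TrialSpec:
    """Design of a simulated replicated variety trial."""

    n_genotypes: int = 16
    replicates: tuple[int, int] = (6, 15)  # uniform range per genotype
    mean_density: float = 561.0  # stems/m²
    mean_diameter: float = 2.1  # mm
    mean_height: float = 0.8  # m
    # Genotypic / residual variances per trait; Vg/(Vg+Ve) is the designed H².
    vg_density: float = 13520.0
    ve_density: float = 3380.0
    vg_diameter: float = 0.0158
    ve_diameter: float = 0.0068
    vg_height: float = 0.00512
    ve_height: float = 0.00128
    agb_beta: float = 7.0e5  # g of biomass per m³ of biovolume
    agb_noise_cv: float = 0.06  # multiplicative noise on AGB
    ear_noise_sd: float = 20.0  # stems/m² discrepancy between ear and stem counts
    seed: int = 0

    @property
    def designed_h2_density(self) -> float:
        return self.vg_density / (self.vg_density + self.ve_density)


def generate_trial(spec: TrialSpec) -> pd.DataFrame:
    """Simulate plot-level traits of a replicated trial. Deterministic per seed.

    Each plot value is mean + genotype effect (variance Vg) + residual
    (variance Ve); traits vary independently across genotypes. AGB is
    β · biovolume · (1 + ε) with ε ~ N(0, agb_noise_cv); ear density equals
    stem density plus a small zero-mean discrepancy.
    """
    if spec.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.replicates
    rows = []
    traits = (
        ("stem_density", spec.mean_density, spec.vg_density, spec.ve_density),
        ("mean_diameter_mm", spec.mean_diameter, spec.vg_diameter, spec.ve_diameter),
        ("height_m", spec.mean_height, spec.vg_height, spec.ve_height),
    )
    geno_eff = {
        name: rng.normal(0.0, math.sqrt(vg), spec.n_genotypes)
        for name, _, vg, _ in traits
    }
    plot = 0
    for g in range(spec.n_genotypes):
        n_rep = int(rng.integers(lo, hi + 1))
        for _ in range(n_rep):
            row = {"plot_id": f"plot_{plot:03d}", "genotype": f"G{g:02d}"}
            for name, mean, _, ve in traits:
                val = mean + geno_eff[name][g] + rng.normal(0.0, math.sqrt(ve))
                row[name] = max(val, 0.05 * mean)  # traits are positive
            rows.append(row)
            plot += 1
    df = pd.DataFrame(rows)
    d_m = df["mean_diameter_mm"] / 1000.0
    df["basal_area"] = math.pi * (d_m / 2.0) ** 2 * df["stem_density"]
    df["biovolume"] = df["basal_area"] * df["height_m"]
    df["ear_density"] = df["stem_density"] + rng.normal(0.0, spec.ear_noise_sd, len(df))
    df["agb"] = spec.agb_beta * df["biovolume"] * (
        1.0 + rng.normal(0.0, spec.agb_noise_cv, len(df))
    )
    return df
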