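"""Gray conversion, profile extraction and diameter estimation."""

import math

import numpy as np
import pytest

from stemscan.diameter import (
    GrayPatch,
    Profile,
    diameter_from_profile,
    extract_profiles,
    measure_stem,
    to_gray,
)
from stemscan.geometry import Box, Detection
from stemscan.synthetic import render_annulus_patch


class TestToGray:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((0, 0, 0), 0.0),
            ((255, 255, 255), 255 * (0.2989 + 0.5870 + 0.1140)),
            ((100, 0, 0), 29.89),
            ((0, 100, 0), 58.70),
            ((0, 0, 100), 11.40),
        ],
    )
    def test_weighted_sum_unrounded(self, rgb, expected):
        assert to_gray(*rgb) == pytest.approx(expected, abs=1e-9)

    def test_linear_in_intensity(self, rng):
        c = rng.uniform(0, 255, 3)
        for alpha in (0.0, 0.3, 1.0):
            assert to_gray(*(alpha * c)) == pytest.approx(alpha * to_gray(*c))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            to_gray(256, 0, 0)
        with pytest.raises(ValueError):
            to_gray(0, -1, 0)


class TestExtractProfiles:
    def test_uniform_patch_gives_constant_profiles(self):
        patch = GrayPatch(np.full((30, 30), 120.0))
        pset = extract_profiles(patch, Box(5, 5, 25, 25))
        assert len(pset.profiles) == 4
        for p in pset.profiles:
            assert np.allclose(p.values, 120.0)
            assert p.positions[0] < 0 < p.positions[-1]

    def test_profiles_clipped_to_box(self):
        patch = GrayPatch(np.zeros((40, 40)))
        box = Box(10, 10, 30, 30)
        pset = extract_profiles(patch, box)
        diag = math.hypot(box.width, box.height)
        for p in pset.profiles:
            length = p.positions[-1] - p.positions[0]
            assert length <= diag + 1e-9
            if p.angle_deg in (0.0, 90.0):
                assert length <= 20 + 1e-9

    def test_annulus_profiles_are_bimodal_and_symmetric(self):
        img, (cx, cy) = render_annulus_patch(radius=10.0)
        half = 12.5
        box = Box(cx - half, cy - half, cx + half, cy + half)
        pset = extract_profiles(GrayPatch(img), box)
        for p in pset.profiles:
            left = p.values[p.positions < 0]
            right = p.values[p.positions > 0]
            ileft = p.positions[p.positions < 0][np.argmax(left)]
            iright = p.positions[p.positions > 0][np.argmax(right)]
            assert ileft == pytest.approx(-10.0, abs=0.6)
            assert iright == pytest.approx(10.0, abs=0.6)

    def test_tiny_box_rejected(self):
        patch = GrayPatch(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            extract_profiles(patch, Box(0, 0, 3, 3))


def synthetic_profile(positions, values):
    return Profile(angle_deg=0.0, positions=np.asarray(positions, float),
                   values=np.asarray(values, float))


class TestDiameterFromProfile:
    def test_two_delta_peaks(self):
        pos = np.arange(-15, 15.5, 0.5)
        vals = np.zeros_like(pos)
        vals[np.isclose(pos, -10.0)] = 100.0
        vals[np.isclose(pos, 10.0)] = 100.0
        assert diameter_from_profile(synthetic_profile(pos, vals)) == pytest.approx(
            20.0, abs=1e-9
        )

    def test_monotone_ramp_is_invalid(self):
        pos = np.arange(-10, 10.5, 0.5)
        assert diameter_from_profile(synthetic_profile(pos, pos + 20.0)) is None

    def test_flat_side_is_invalid(self):
        pos = np.arange(-10, 10.5, 0.5)
        vals = np.where(pos > 0, np.exp(-((pos - 5) ** 2)), 1.0)
        assert diameter_from_profile(synthetic_profile(pos, vals)) is None

    def test_affine_rescaling_leaves_diameter_unchanged(self):
        img, (cx, cy) = render_annulus_patch(radius=8.0)
        box = Box(cx - 10, cy - 10, cx + 10, cy + 10)
        pset = extract_profiles(GrayPatch(img), box)
        pset2 = extract_profiles(GrayPatch(img * 0.5 + 40.0), box)
        for p, q in zip(pset.profiles, pset2.profiles):
            assert diameter_from_profile(p) == pytest.approx(
                diameter_from_profile(q), abs=1e-9
            )


class TestMeasureStem:
    def measure(self, radius, resolution=0.18, noise=0.0, seed=0):
        img, (cx, cy) = render_annulus_patch(radius=radius, noise_sigma=noise,
                                             seed=seed)
        half = 1.25 * radius
        det = Detection(box=Box(cx - half, cy - half, cx + half, cy + half),
                        score=1.0)
        return measure_stem(GrayPatch(img), det, resolution)

    @pytest.mark.parametrize("radius", [5.0, 8.0, 11.0, 15.0])
    def test_recovers_ring_center_diameter(self, radius):
        m = self.measure(radius)
        assert m.valid
        assert m.mean_diameter_px == pytest.approx(2 * radius, abs=1.0)
        assert m.diameter_mm == pytest.approx(m.mean_diameter_px * 0.18)

    def test_circular_stem_directions_agree(self):
        m = self.measure(10.0)
        usable = [d for d in m.per_direction_px if d is not None]
        assert len(usable) == 4
        assert max(usable) - min(usable) <= 1.0  # two sampling steps

    def test_ellipse_mean_lies_between_axes(self):
        # Ring along an ellipse with semi-axes 8 and 10 px.
        a, b = 8.0, 10.0
        size = 34
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        cx = cy = size / 2
        re = np.hypot((xx + 0.5 - cx) / a, (yy + 0.5 - cy) / b)
        img = 70 + 130 * np.exp(-((re - 1.0) ** 2) * (a * b) / (2 * 1.2**2))
        det = Detection(box=Box(cx - 14, cy - 14, cx + 14, cy + 14), score=1.0)
        m = measure_stem(GrayPatch(img), det, 0.18)
        assert m.valid
        assert 2 * a < m.mean_diameter_px < 2 * b

    def test_single_valid_direction_is_insufficient(self):
        # A ring visible only in a narrow vertical band with a brightness
        # ramp elsewhere: the vertical profile sees both borders, the other
        # three rise monotonically to the box edge (endpoint maxima).
        size = 34
        cx = cy = size / 2
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        dx = xx + 0.5 - cx
        rr = np.hypot(dx, yy + 0.5 - cy)
        ring = 130 * np.exp(-((rr - 10.0) ** 2) / (2 * 1.2**2))
        img = 70 + ring * np.exp(-((dx / 3.0) ** 2)) + 3.0 * np.abs(dx)
        det = Detection(box=Box(cx - 13, cy - 13, cx + 13, cy + 13), score=1.0)
        m = measure_stem(GrayPatch(img), det, 0.18)
        valid_dirs = [d for d in m.per_direction_px if d is not None]
        assert len(valid_dirs) == 1
        assert not m.valid

    def test_mean_and_mm_conversion(self):
        m = self.measure(8.0, resolution=0.12)
        assert m.diameter_mm == pytest.approx(m.mean_diameter_px * 0.12)

    def test_nonpositive_resolution_rejected(self):
        img, (cx, cy) = render_annulus_patch(radius=8.0)
        det = Detection(box=Box(cx - 10, cy - 10, cx + 10, cy + 10), score=1.0)
        with pytest.raises(ValueError):
            measure_stem(GrayPatch(img), det, 0.0)
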