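import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import torsometry as tm
from torsometry.geometry import (
    THETA_GRID,
    align_slice,
    compute_centroid,
    detect_sp,
    estimate_vb_line,
    locate_backside_anchors,
    moving_average_filter,
    resample_angular,
    to_polar,
)


def _contour_from_radii(theta_deg, r, **kw):
    t = np.radians(theta_deg)
    return tm.RawContour(points=np.column_stack([r * np.cos(t), r * np.sin(t)]), level_label=None, **kw)


class TestCentroidAndPolar:
    def test_centroid_of_offset_circle(self):
        ang = np.radians(np.arange(0, 360, 2.0))
        pts = np.column_stack([2 + 5 * np.cos(ang), 3 + 5 * np.sin(ang)])
        c = compute_centroid(tm.RawContour(level_label=None, points=pts))
        assert c == pytest.approx([2.0, 3.0])

    def test_centroid_matches_direct_mean(self):
        contour, _ = tm.generate_contour(tm.SyntheticTorsoSpec(hump_amplitude=10.0), "T8")
        assert compute_centroid(contour) == pytest.approx(contour.points.mean(axis=0))

    def test_square_polar_radii(self):
        s = np.linspace(-1, 1, 41)
        edges = [np.column_stack([s, np.full_like(s, -1.0)]),
                 np.column_stack([np.full_like(s, 1.0), s]),
                 np.column_stack([s[::-1], np.full_like(s, 1.0)]),
                 np.column_stack([np.full_like(s, -1.0), s[::-1]])]
        square = tm.RawContour(level_label=None, points=np.concatenate(edges))
        polar = to_polar(square, (0.0, 0.0))
        r_at = lambda a: polar.r[np.argmin(np.abs(polar.theta - a))]
        assert r_at(0.0) == pytest.approx(1.0)
        assert r_at(45.0) == pytest.approx(np.sqrt(2.0))

    def test_circle_constant_radius(self, circle_contour):
        polar = to_polar(circle_contour, (0.0, 0.0))
        assert polar.r == pytest.approx(np.full(len(circle_contour), 100.0))

    def test_origin_outside_rejected(self, circle_contour):
        with pytest.raises(tm.GeometryError):
            to_polar(circle_contour, (200.0, 200.0))

    def test_polar_round_trip(self):
        contour, _ = tm.generate_contour(tm.SyntheticTorsoSpec(hump_amplitude=8.0), "T8")
        origin = compute_centroid(contour)
        polar = to_polar(contour, origin)
        rebuilt = polar.to_points()
        # reorder the originals with the same angle sort to_polar applies
        rel = contour.points - origin
        theta = tm.slices.wrap_deg(np.degrees(np.arctan2(rel[:, 1], rel[:, 0])))
        expected = contour.points[np.argsort(theta, kind="stable")]
        assert np.allclose(expected, rebuilt, rtol=1e-9, atol=1e-9)


class TestDetectSP:
    def test_midline_dip_recovered(self):
        contour, truth = tm.generate_contour(tm.SyntheticTorsoSpec(noise_sd=0.0), "T8")
        polar = to_polar(contour, compute_centroid(contour))
        det = detect_sp(polar)
        assert det.angle == pytest.approx(truth.sp_angle, abs=1.0)
        assert not det.warnings

    def test_off_midline_dip_recovered(self):
        # a sharp dip: on the sloped superellipse baseline a broad shallow dip
        # placed off-midline is genuinely not the radius minimum
        spec = tm.SyntheticTorsoSpec(
            dip_depth=12.0, dip_width=4.0, dip_angle=-20.0, noise_sd=0.0
        )
        contour, truth = tm.generate_contour(spec, "T8")
        polar = to_polar(contour, compute_centroid(contour))
        assert detect_sp(polar).angle == pytest.approx(-110.0, abs=1.0)

    def test_circle_flat_minimum_returns_midline_with_warning(self, circle_contour):
        det = detect_sp(to_polar(circle_contour, (0.0, 0.0)))
        assert det.angle == pytest.approx(-90.0)
        assert any("low-confidence" in w for w in det.warnings)

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(tm.ValidationError):
            moving_average_filter(np.ones(360), 4)


class TestAlignSlice:
    def test_rotated_contour_unrotated(self):
        contour, truth = tm.generate_contour(tm.SyntheticTorsoSpec(noise_sd=0.0), "T8")
        phi = 30.0
        t = np.radians(phi)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        rotated = tm.RawContour(level_label=None, points=contour.points @ rot.T)
        polar = to_polar(rotated, compute_centroid(rotated))
        aligned = align_slice(polar, truth.sp_angle + phi)
        assert aligned.rotation_applied == pytest.approx(-30.0, abs=1e-9)
        assert float(np.argmin(aligned.radius[150:211])) + 150 == 180  # SP dip at 0 deg

    def test_already_aligned_is_near_identity(self):
        contour, truth = tm.generate_contour(tm.SyntheticTorsoSpec(noise_sd=0.0), "T8")
        polar = to_polar(contour, compute_centroid(contour))
        aligned = align_slice(polar, detect_sp(polar).angle)
        assert abs(aligned.rotation_applied) < 1.0

    def test_circle_with_dip_aligned_by_step_two_alone(self):
        theta = np.arange(-180.0, 180.0, 0.5)
        r = 100.0 - 6.0 * np.exp(-0.5 * ((tm.slices.wrap_deg(theta + 70.0)) / 8.0) ** 2)
        contour = _contour_from_radii(theta, r)
        polar = to_polar(contour, compute_centroid(contour))
        aligned = align_slice(polar, detect_sp(polar).angle)
        assert int(np.argmin(aligned.radius)) == 180  # dip moved to 0 deg

    @pytest.mark.parametrize("phi", [1.0, 22.5, 37.0, -90.5, 180.0])
    def test_rotation_equivariance(self, phi):
        contour, truth = tm.generate_contour(
            tm.SyntheticTorsoSpec(hump_amplitude=12.0, noise_sd=0.0), "T8"
        )
        polar = to_polar(contour, compute_centroid(contour))
        base = align_slice(polar, truth.sp_angle)
        t = np.radians(phi)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        pre = tm.RawContour(level_label=None, points=contour.points @ rot.T)
        polar2 = to_polar(pre, compute_centroid(pre))
        out = align_slice(polar2, truth.sp_angle + phi)
        delta = tm.slices.wrap_deg(out.rotation_applied - base.rotation_applied + phi)
        assert abs(float(delta)) < 1e-9
        assert np.max(np.abs(out.radius - base.radius) / base.radius) < 1e-6


class TestResample:
    def test_constant_contour_is_fixed_point(self):
        rng = np.random.default_rng(0)
        theta = np.sort(rng.uniform(-180.0, 180.0, 400))
        polar = tm.PolarContour(theta=theta, r=np.full(400, 5.0), origin=np.zeros(2))
        aligned = resample_angular(polar)
        assert aligned.radius == pytest.approx(np.full(361, 5.0))
        assert aligned.mean_radius == pytest.approx(5.0)

    def test_linear_ramp_reproduced_exactly(self):
        theta = np.arange(-180.0, 180.0, 0.5)
        polar = tm.PolarContour(theta=theta, r=100.0 + theta / 10.0, origin=np.zeros(2))
        grid = resample_angular(polar).radius[:360]
        expected = 100.0 + THETA_GRID[:360] / 10.0
        assert np.max(np.abs(grid - expected) / expected) < 1e-9

    def test_masked_gap_interpolated_with_warning(self):
        theta = np.arange(-180.0, 180.0, 1.0)
        keep = ~((theta > 80.0) & (theta < 100.0))
        polar = tm.PolarContour(theta=theta[keep], r=np.full(keep.sum(), 7.0), origin=np.zeros(2))
        aligned = resample_angular(polar)
        assert any("gap" in w for w in aligned.warnings)
        assert aligned.radius == pytest.approx(np.full(361, 7.0))

    @given(st.floats(1.0, 500.0))
    def test_mean_radius_is_grid_mean(self, scale):
        rng = np.random.default_rng(3)
        r = scale * (1.0 + 0.2 * rng.random(720))
        polar = tm.PolarContour(
            theta=np.arange(-180.0, 180.0, 0.5), r=r, origin=np.zeros(2)
        )
        aligned = resample_angular(polar)
        assert aligned.mean_radius == pytest.approx(aligned.radius[:360].mean())


class TestAnchorsAndVBLine:
    def test_default_anchor_separation(self, circle_aligned):
        anchors = locate_backside_anchors(circle_aligned)
        assert (anchors.brsp_angle, anchors.blsp_angle) == (70.0, -70.0)

    @pytest.mark.parametrize("sep", [0, 180, -5])
    def test_invalid_separation(self, circle_aligned, sep):
        with pytest.raises(tm.ValidationError):
            locate_backside_anchors(circle_aligned, sep)

    def test_right_angle_separation(self, circle_aligned):
        anchors = locate_backside_anchors(circle_aligned, 90)
        assert anchors.brsp_angle == 90.0

    def test_vb_center_above_sp_point(self, circle_aligned):
        vb = estimate_vb_line(circle_aligned, 30.0)
        assert vb.vb_center == pytest.approx((0.0, -70.0))

    def test_zero_offset_rejected(self, circle_aligned):
        with pytest.raises(tm.ValidationError):
            estimate_vb_line(circle_aligned, 0.0)

    def test_offset_beyond_diameter_rejected(self, circle_aligned):
        with pytest.raises(tm.ValidationError):
            estimate_vb_line(circle_aligned, 2 * circle_aligned.mean_radius + 1.0)
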