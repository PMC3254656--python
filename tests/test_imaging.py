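"""Image-quantification operators: preprocessing, watershed, measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoshape.imaging import (
    LABEL_AB,
    LABEL_BOUNDARY,
    LABEL_EXTERIOR,
    LABEL_P1,
    ImageStack,
    Kymograph,
    LabelVolume,
    classify_contact,
    curve_depth_2d,
    digitize_sphere_labels,
    fill_boundaries,
    flow_velocity,
    normalize_intensity,
    preprocess_stack,
    region_volume,
    size_symmetry,
    watershed_segment,
)
from embryoshape.synth import SynthConfig, synth_kymograph


class TestPreprocess:
    def test_constant_image_preserved(self):
        s = ImageStack(np.full((10, 20, 20), 7.0), (0.733, 0.244, 0.244))
        out = preprocess_stack(s)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-6)

    def test_output_spacing_is_cubic_default(self):
        s = ImageStack(np.zeros((10, 20, 20)), (0.733, 0.244, 0.244))
        assert preprocess_stack(s).spacing == (0.733, 0.733, 0.733)

    def test_total_intensity_conserved_for_interior_signal(self):
        rng = np.random.default_rng(0)
        data = np.zeros((24, 60, 60))
        data[8:16, 20:40, 20:40] = rng.uniform(1, 3, (8, 20, 20))
        sp = (0.733, 0.244, 0.244)
        s = ImageStack(data, sp)
        out = preprocess_stack(s)
        mass_in = data.sum() * np.prod(sp)
        mass_out = out.data.sum() * out.spacing[0] ** 3
        assert mass_out == pytest.approx(mass_in, rel=0.01)

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((4, 4, 4)), (0.5, -0.5, 0.5))


class TestWatershed:
    @staticmethod
    def two_blob_stack(n=40):
        # membrane ridges around two spherical cells in an empty volume
        zz, yy, xx = np.indices((n, n, n), dtype=float)
        c1, c2 = np.array([n / 2, n / 2, n * 0.3]), np.array([n / 2, n / 2, n * 0.7])
        r1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
        r2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
        mem = np.exp(-((r1 - 8) ** 2) / 2) + np.exp(-((r2 - 8) ** 2) / 2)
        return ImageStack(mem, (1.0, 1.0, 1.0)), c1.astype(int), c2.astype(int)

    def test_markers_keep_their_labels(self):
        stack, c1, c2 = self.two_blob_stack()
        markers = {LABEL_AB: tuple(c1), LABEL_P1: tuple(c2), LABEL_EXTERIOR: (0, 0, 0)}
        lv = watershed_segment(stack, markers)
        assert lv.labels[tuple(c1)] == LABEL_AB
        assert lv.labels[tuple(c2)] == LABEL_P1
        assert lv.labels[0, 0, 0] == LABEL_EXTERIOR

    def test_labels_partition_the_volume(self):
        stack, c1, c2 = self.two_blob_stack()
        lv = watershed_segment(
            stack, {LABEL_AB: tuple(c1), LABEL_P1: tuple(c2), LABEL_EXTERIOR: (0, 0, 0)}
        )
        counts = {lab: int((lv.labels == lab).sum())
                  for lab in (LABEL_BOUNDARY, LABEL_AB, LABEL_P1, LABEL_EXTERIOR)}
        assert sum(counts.values()) == stack.data.size
        assert all(c > 0 for c in counts.values())

    def test_coincident_markers_rejected(self):
        stack, c1, _ = self.two_blob_stack(20)
        with pytest.raises(ValueError, match="distinct"):
            watershed_segment(stack, {LABEL_AB: tuple(c1), LABEL_P1: tuple(c1)})

    def test_fill_boundaries_removes_the_boundary_class(self):
        stack, c1, c2 = self.two_blob_stack()
        lv = watershed_segment(
            stack, {LABEL_AB: tuple(c1), LABEL_P1: tuple(c2), LABEL_EXTERIOR: (0, 0, 0)}
        )
        filled = fill_boundaries(lv)
        assert not np.any(filled == LABEL_BOUNDARY)
        # non-boundary voxels keep their labels
        keep = lv.labels != LABEL_BOUNDARY
        np.testing.assert_array_equal(filled[keep], lv.labels[keep])


class TestRegionVolume:
    @pytest.mark.parametrize("radius", [8, 15, 30])
    def test_digitized_sphere_within_1pc(self, radius):
        lv = digitize_sphere_labels(radius)
        v = region_volume(lv, LABEL_AB)
        assert v == pytest.approx(4 / 3 * np.pi * radius**3, rel=0.01)

    def test_no_boundary_limit(self):
        labels = np.full((5, 5, 5), LABEL_AB, dtype=np.int32)
        lv = LabelVolume(labels, spacing=2.0)
        assert region_volume(lv, LABEL_AB) == pytest.approx(125 * 8.0)

    def test_cube_with_full_shell_documents_corner_bias(self):
        # 10^3 region wrapped in a 1-voxel boundary: the estimator counts
        # 1000 + 600/2 = 1300 voxels, far below the enclosed 12^3 cube —
        # the half-boundary correction is exact only for smooth shapes
        labels = np.full((14, 14, 14), LABEL_EXTERIOR, dtype=np.int32)
        labels[1:13, 1:13, 1:13] = LABEL_BOUNDARY
        labels[2:12, 2:12, 2:12] = LABEL_AB
        lv = LabelVolume(labels, spacing=1.0)
        # face-adjacent boundary voxels: 6 faces of 10x10
        assert region_volume(lv, LABEL_AB) == pytest.approx(1000 + 600 / 2)

    def test_absent_region_raises(self):
        lv = LabelVolume(np.full((4, 4, 4), LABEL_EXTERIOR, dtype=np.int32), 1.0)
        with pytest.raises(ValueError, match="not present"):
            region_volume(lv, LABEL_AB)


def make_arc(R, rho, n=101, toward=+1):
    """Circular arc with chord half-length rho, bulging toward +y if toward=+1."""
    th_max = np.arcsin(rho / R)
    th = np.linspace(-th_max, th_max, n)
    return np.column_stack([R * np.sin(th), toward * (R * np.cos(th) - np.sqrt(R**2 - rho**2))])


class TestCurveDepth2D:
    def test_straight_trace_is_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        assert curve_depth_2d(pts, ap_axis=[0, 1]) == 0.0

    @pytest.mark.parametrize(("R", "rho"), [(20.0, 12.0), (8.0, 3.0), (50.0, 10.0)])
    def test_sagitta_closed_form(self, R, rho):
        sag = R - np.sqrt(R**2 - rho**2)
        assert curve_depth_2d(make_arc(R, rho), [0, 1]) == pytest.approx(sag, abs=1e-6)

    def test_sign_convention(self):
        # bulge toward P1 (along the AP axis) positive, toward AB negative
        arc = make_arc(20.0, 12.0)
        assert curve_depth_2d(arc, [0, 1]) > 0
        assert curve_depth_2d(make_arc(20.0, 12.0, toward=-1), [0, 1]) < 0
        assert curve_depth_2d(arc, [0, 1]) == pytest.approx(
            -curve_depth_2d(make_arc(20.0, 12.0, toward=-1), [0, 1])
        )

    @settings(deadline=None, max_examples=25)
    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_rigid_invariance(self, angle, tx, ty):
        arc = make_arc(20.0, 12.0)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = arc @ R.T + [tx, ty]
        ap = R @ np.array([0.0, 1.0])
        d0 = curve_depth_2d(arc, [0, 1])
        assert curve_depth_2d(moved, ap) == pytest.approx(d0, abs=1e-9)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            curve_depth_2d(np.zeros((2, 2)), [0, 1])


class TestClassifyContact:
    def test_collinear_is_flat(self):
        assert classify_contact([0, 0], [1, 0], [2, 0]) == "flat"

    def test_160_degree_boundary_is_strict(self):
        def points_for(angle_deg):
            half = np.radians(180 - angle_deg) / 2
            return [-np.cos(half), np.sin(half)], [0, 0], [np.cos(half), np.sin(half)]

        a, m, b = points_for(159.0)
        assert classify_contact(a, m, b) == "curved"
        a, m, b = points_for(160.0)
        assert classify_contact(a, m, b) == "flat"

    def test_right_angle_is_curved(self):
        assert classify_contact([1, 0], [0, 0], [0, 1]) == "curved"

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            classify_contact([0, 0], [0, 0], [1, 1])


class TestSizeSymmetry:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [(20.0, 20.0, True), (20.0, 18.0, True), (18.0, 20.0, True), (22.0, 15.0, False)],
    )
    def test_threshold_inclusive(self, a, b, expected):
        assert size_symmetry(a, b) is expected

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            size_symmetry(0.0, 10.0)


class TestNormalizeIntensity:
    def test_constant_equal_traces_normalize_to_one(self):
        t = np.arange(10.0)
        tr = normalize_intensity(t, np.full(10, 42.0), np.full(10, 42.0), 1.0, 1.0)
        np.testing.assert_allclose(tr.I_AB_norm, 1.0)
        np.testing.assert_allclose(tr.I_P1_norm, 1.0)

    @settings(deadline=None, max_examples=20)
    @given(gain=st.floats(0.01, 100.0))
    def test_gain_invariance(self, gain):
        t = np.arange(8.0)
        iab = 100 + 5 * t
        ip1 = np.full(8, 90.0)
        base = normalize_intensity(t, iab, ip1, 1.3, 1.0)
        scaled = normalize_intensity(t, gain * iab, gain * ip1, 1.3, 1.0)
        np.testing.assert_allclose(scaled.I_AB_norm, base.I_AB_norm, rtol=1e-9)
        np.testing.assert_allclose(scaled.I_P1_norm, base.I_P1_norm, rtol=1e-9)

    def test_direct_ratio(self):
        # merged-region mean fixed at 100 -> trace at 125 normalizes to 1.25
        t = np.arange(5.0)
        tr = normalize_intensity(t, np.full(5, 125.0), np.full(5, 75.0), 1.0, 1.0)
        np.testing.assert_allclose(tr.I_AB_norm, 1.25)

    def test_nonpositive_divisor_raises(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.arange(3.0), np.zeros(3), np.zeros(3), 1.0, 1.0)


class TestFlowVelocity:
    @staticmethod
    def kymo_with_slopes(slopes):
        t = np.arange(0, 5, 0.1)
        lines = [np.column_stack([t, 2.0 + i + s * t]) for i, s in enumerate(slopes)]
        return Kymograph(np.zeros((1, 1)), 0.1, 0.1, lines)

    def test_exact_slopes(self):
        assert flow_velocity(self.kymo_with_slopes([2.4, 2.4, 2.4])) == pytest.approx(2.4)

    def test_mean_of_three(self):
        assert flow_velocity(self.kymo_with_slopes([0.5, 0.6, 0.7])) == pytest.approx(0.6)

    def test_too_few_lines_raise(self):
        with pytest.raises(ValueError):
            flow_velocity(self.kymo_with_slopes([1.0]))

    def test_noisy_kymograph_recovery_within_10pc(self):
        estimates = [
            flow_velocity(synth_kymograph(0.6, SynthConfig(seed=s, kymo_noise=0.3)))
            for s in range(10)
        ]
        assert np.all(np.abs(np.array(estimates) - 0.6) <= 0.06)
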