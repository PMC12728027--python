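"""Cobb angles: inflection search, local tangents, paired comparison."""

import numpy as np
import pytest

from spinalign.cobb import (
    cobb_frontal,
    cobb_sagittal,
    cobb_segments,
    compare_cobb,
    find_inflections,
    local_tangent,
)
from spinalign.curves import smooth_curve
from spinalign.phantom import PhantomSpec, _SagittalCurve
from spinalign.types import Plane, SingleCurveError, SpinalignError
from spinalign.validation import dense_cobb_reference


def sine_curve(A=10.0, L=200.0, span=None, n=200):
    span = L if span is None else span
    y = np.linspace(0, span, n)
    pts = np.column_stack([A * np.sin(2 * np.pi * y / L), y, np.zeros_like(y)])
    return smooth_curve(pts, smoothing="auto", n_samples=100)


def sagittal_curve(kyphosis=40.0, lordosis=45.0, length=450.0, n=200):
    sc = _SagittalCurve(
        PhantomSpec(kyphosis_angle_deg=kyphosis, lordosis_angle_deg=lordosis,
                    spine_length_mm=length)
    )
    y = np.linspace(0, length, n)
    pts = np.column_stack([np.zeros_like(y), y, sc.z(y)])
    return smooth_curve(pts, smoothing="auto", n_samples=120)


class TestFindInflections:
    def test_straight_line_has_no_interior_inflections(self):
        y = np.linspace(0, 200, 50)
        curve = smooth_curve(np.column_stack([0.3 * y, y, np.zeros_like(y)]))
        infl = find_inflections(curve, Plane.FRONTAL)
        assert infl.interior.size == 0
        np.testing.assert_allclose(infl.breaks, [0.0, 200.0])

    def test_sine_inflection_located_at_half_period(self):
        infl = find_inflections(sine_curve(A=10, L=200), Plane.FRONTAL)
        assert len(infl.interior) == 1
        assert infl.interior[0] == pytest.approx(100.0, abs=0.5)

    def test_double_sagittal_curve_has_one_interior_inflection(self):
        infl = find_inflections(sagittal_curve(), Plane.SAGITTAL)
        assert len(infl.interior) == 1
        # the construction places the junction at 40% of the length
        assert infl.interior[0] == pytest.approx(180.0, abs=5.0)


class TestLocalTangent:
    def test_straight_line_slope_exact_for_any_window(self):
        y = np.linspace(0, 200, 50)
        curve = smooth_curve(np.column_stack([0.5 * y - 7, y, np.zeros_like(y)]))
        for w in (10.0, 30.0, 100.0):
            assert local_tangent(curve, Plane.FRONTAL, 100.0, w) == pytest.approx(0.5, abs=1e-8)

    def test_sine_inflection_slope_within_2pct_at_20mm_window(self):
        # analytic slope at the inflection of A sin(2 pi y / L): -2 pi A / L
        curve = sine_curve(A=10, L=200)
        slope = local_tangent(curve, Plane.FRONTAL, 100.0, window_mm=20.0)
        assert slope == pytest.approx(-2 * np.pi * 10 / 200, rel=0.02)

    def test_slope_near_zero_at_extremum(self):
        curve = sine_curve(A=10, L=200)
        assert abs(local_tangent(curve, Plane.FRONTAL, 50.0, window_mm=20.0)) < 0.01

    def test_oversized_window_falls_back_to_global_fit(self):
        curve = sine_curve(A=5, L=200)
        with pytest.warns(UserWarning, match="global fit"):
            local_tangent(curve, Plane.FRONTAL, 100.0, window_mm=1e6)


class TestCobbFrontal:
    def test_straight_vertical_line_is_zero(self):
        y = np.linspace(0, 400, 60)
        curve = smooth_curve(np.column_stack([np.zeros_like(y), y, np.zeros_like(y)]))
        _, primary = cobb_frontal(curve)
        assert primary.angle_deg == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("A,L", [(5.0, 200.0), (10.0, 200.0), (20.0, 400.0)])
    def test_matches_analytic_tangent_formula(self, A, L):
        _, primary = cobb_frontal(sine_curve(A=A, L=L))
        truth = 2 * np.degrees(np.arctan(2 * np.pi * A / L))
        assert primary.angle_deg == pytest.approx(truth, abs=1.0)

    def test_monotone_in_amplitude(self):
        angles = [cobb_frontal(sine_curve(A=A, L=300))[1].angle_deg for A in (2, 5, 10, 20)]
        assert np.all(np.diff(angles) > 0)

    def test_invariant_to_in_plane_translation(self):
        y = np.linspace(0, 200, 200)
        pts = np.column_stack([10 * np.sin(2 * np.pi * y / 200), y, np.zeros_like(y)])
        a0 = cobb_frontal(smooth_curve(pts))[1].angle_deg
        a1 = cobb_frontal(smooth_curve(pts + [55.0, 0.0, -14.0]))[1].angle_deg
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_agrees_with_dense_differentiation_oracle(self):
        curve = sine_curve(A=15, L=300)
        _, primary = cobb_frontal(curve)
        assert primary.angle_deg == pytest.approx(
            dense_cobb_reference(curve, Plane.FRONTAL), abs=1.0
        )


class TestCobbSagittal:
    def test_double_curve_recovers_prescribed_angles(self):
        kyph, lord = cobb_sagittal(sagittal_curve(kyphosis=40.0, lordosis=45.0))
        assert kyph.angle_deg == pytest.approx(40.0, abs=1.0)
        assert lord.angle_deg == pytest.approx(45.0, abs=1.0)
        assert kyph.lower_y > lord.lower_y  # kyphotic segment is cranial

    def test_mirrored_profile_swaps_labels_keeps_angles(self):
        curve = sagittal_curve(kyphosis=38.0, lordosis=50.0)
        mirrored = smooth_curve(curve.points * np.array([1.0, 1.0, -1.0]), n_samples=120)
        k0, l0 = cobb_sagittal(curve)
        k1, l1 = cobb_sagittal(mirrored)
        assert k1.angle_deg == pytest.approx(l0.angle_deg, abs=0.5)
        assert l1.angle_deg == pytest.approx(k0.angle_deg, abs=0.5)

    def test_monotone_profile_raises_single_curve_error(self):
        y = np.linspace(0, 400, 60)
        pts = np.column_stack([np.zeros_like(y), y, 0.2 * y])
        with pytest.raises(SingleCurveError):
            cobb_sagittal(smooth_curve(pts))

    def test_single_arc_segment_matches_dense_oracle(self):
        # circular arc in the sagittal plane: generic segment Cobb vs
        # the central-difference reference
        S, sagitta = 400.0, 25.0
        R = (sagitta**2 + (S / 2) ** 2) / (2 * sagitta)
        y = np.linspace(0, S, 300)
        z = np.sqrt(R**2 - (y - S / 2) ** 2) - np.sqrt(R**2 - (S / 2) ** 2)
        curve = smooth_curve(np.column_stack([np.zeros_like(y), y, z]), n_samples=150)
        segs = cobb_segments(curve, Plane.SAGITTAL)
        assert len(segs) == 1
        assert segs[0].angle_deg == pytest.approx(
            dense_cobb_reference(curve, Plane.SAGITTAL), abs=1.0
        )


class TestCompareCobb:
    def test_identical_lists(self):
        out = compare_cobb([10.0, 20.0, 30.0, 40.0], [10.0, 20.0, 30.0, 40.0])
        assert out["median_difference"] == 0.0
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constant_shift(self):
        a = np.array([10.0, 25.0, 33.0, 47.0])
        out = compare_cobb(a, a + 3.0)
        assert out["median_difference"] == pytest.approx(-3.0)
        assert out["iqr_difference"] == pytest.approx(0.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_hand_computed_median_and_iqr(self):
        # differences (1, -2, 4): median 1; linear-interpolation
        # quartiles of the sorted sample (-2, 1, 4) are -0.5 and 2.5
        out = compare_cobb([1.0, -2.0, 4.0], [0.0, 0.0, 0.0])
        assert out["median_difference"] == pytest.approx(1.0)
        assert out["iqr_difference"] == pytest.approx(3.0)

    def test_fisher_ci_brackets_r(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(10, 50, 30)
        b = a + rng.normal(0, 4, 30)
        out = compare_cobb(a, b)
        lo, hi = out["r_ci95"]
        assert lo < out["pearson_r"] < hi

    def test_too_few_pairs_raise(self):
        with pytest.raises(SpinalignError):
            compare_cobb([1.0, 2.0], [1.0, 2.0])
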