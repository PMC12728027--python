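"""Smoothing splines, rotation-only Procrustes, per-plane correlation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinalign.curves import (
    pcc_per_plane,
    procrustes_align,
    resample_pair,
    smooth_curve,
)
from spinalign.types import Plane, RigidTransform, SpinalignError, UndefinedCorrelationError


def sine_polyline(amplitude=10.0, wavelength=400.0, span=400.0, n=60):
    y = np.linspace(0, span, n)
    return np.column_stack([amplitude * np.sin(2 * np.pi * y / wavelength), y, np.zeros_like(y)])


class TestSmoothCurve:
    @pytest.mark.parametrize("smoothing", ["auto", 0.0, 1e3])
    def test_straight_line_reproduced_for_any_penalty(self, smoothing):
        y = np.linspace(0, 100, 20)
        line = np.column_stack([0.5 * y + 3, y, -0.2 * y + 1])
        curve = smooth_curve(line, smoothing=smoothing, n_samples=50)
        np.testing.assert_allclose(curve.points[:, 0], 0.5 * curve.y_grid + 3, atol=1e-8)
        np.testing.assert_allclose(curve.points[:, 2], -0.2 * curve.y_grid + 1, atol=1e-8)

    def test_gcv_recovers_noisy_sine_within_1mm(self):
        rng = np.random.default_rng(123)
        line = sine_polyline()
        noisy = line + np.column_stack(
            [rng.normal(0, 0.5, len(line)), np.zeros(len(line)), np.zeros(len(line))]
        )
        curve = smooth_curve(noisy, smoothing="auto", n_samples=400)
        truth = 10 * np.sin(2 * np.pi * curve.y_grid / 400)
        assert np.max(np.abs(curve.points[:, 0] - truth)) < 1.0

    def test_sample_contract(self):
        curve = smooth_curve(sine_polyline(), n_samples=100)
        assert curve.n_samples == 100
        assert curve.y_range == (0.0, 400.0)
        dy = np.diff(curve.y_grid)
        np.testing.assert_allclose(dy, dy[0])

    def test_points_evaluate_stored_splines(self):
        curve = smooth_curve(sine_polyline(), n_samples=40)
        np.testing.assert_array_equal(curve.points, curve.evaluate(curve.y_grid))

    def test_too_few_points_rejected(self):
        with pytest.raises(SpinalignError, match=">= 4"):
            smooth_curve(np.zeros((3, 3)))

    def test_four_points_supported(self):
        y = np.array([0.0, 30.0, 70.0, 100.0])
        curve = smooth_curve(np.column_stack([y * 0.1, y, y * 0.0]), n_samples=20)
        np.testing.assert_allclose(curve.points[:, 0], 0.1 * curve.y_grid, atol=1e-9)


class TestProcrustes:
    def test_self_alignment_is_exact(self):
        pts = smooth_curve(sine_polyline()).points
        aligned, disparity, t = procrustes_align(pts, pts)
        np.testing.assert_allclose(aligned, pts, atol=1e-9)
        assert disparity == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigidly_moved_curve(self):
        pts = smooth_curve(sine_polyline()).points
        moved = RigidTransform(
            Rotation.from_euler("z", 10, degrees=True).as_matrix(), [50.0, -20.0, 5.0]
        ).apply(pts)
        aligned, disparity, _ = procrustes_align(pts, moved)
        np.testing.assert_allclose(aligned, pts, atol=1e-9)
        assert disparity < 1e-15 * len(pts)

    def test_centroid_size_never_changes(self, rng):
        ref = rng.normal(size=(50, 3)) * 30
        mov = rng.normal(size=(50, 3)) * 30
        aligned, _, _ = procrustes_align(ref, mov)
        size = lambda p: np.sqrt(np.mean(np.sum((p - p.mean(0)) ** 2, axis=1)))
        assert size(aligned) == pytest.approx(size(mov), abs=1e-9)

    def test_sample_count_mismatch_raises(self, rng):
        with pytest.raises(SpinalignError):
            procrustes_align(rng.normal(size=(10, 3)), rng.normal(size=(12, 3)))

    def test_disparity_invariant_to_rigid_pretransform(self, rng):
        ref = smooth_curve(sine_polyline()).points
        mov = ref + rng.normal(0, 1.0, ref.shape)
        _, d0, _ = procrustes_align(ref, mov)
        pre = RigidTransform(Rotation.random(random_state=4).as_matrix(), [100.0, 3.0, -8.0])
        _, d1, _ = procrustes_align(ref, pre.apply(mov))
        assert d1 == pytest.approx(d0, abs=1e-6)


class TestResamplePair:
    def test_common_grid_covers_overlap(self):
        a = smooth_curve(sine_polyline(span=400.0))
        b_line = sine_polyline(span=300.0)
        b_line[:, 1] += 50  # y in [50, 350]
        b = smooth_curve(b_line)
        ra, rb = resample_pair(a, b, 80)
        assert ra.y_range == rb.y_range == (50.0, 350.0)
        assert ra.n_samples == rb.n_samples == 80


class TestPcc:
    def test_identical_sequences_give_exactly_one(self, rng):
        x = rng.normal(size=50)
        assert pcc_per_plane(x, x.copy(), Plane.FRONTAL) == 1.0

    def test_negated_sequences_give_exactly_minus_one(self, rng):
        x = rng.normal(size=50)
        assert pcc_per_plane(x, -x, Plane.FRONTAL) == -1.0

    def test_hand_computed_value(self):
        # r of (0,1,2) vs (0,1,3) is 1.5 / (1 * sqrt(7/3)) = 0.9820 (4 d.p.)
        assert pcc_per_plane(
            np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0]), Plane.FRONTAL
        ) == pytest.approx(0.9820, abs=5e-5)

    def test_matches_two_pass_covariance_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            a, b = rng.normal(size=n), rng.normal(size=n)
            brute = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
            )
            assert pcc_per_plane(a, b, Plane.SAGITTAL) == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_positive_affine_rescaling(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        base = pcc_per_plane(a, b, Plane.FRONTAL)
        assert pcc_per_plane(3.7 * a + 11, b, Plane.FRONTAL) == pytest.approx(base, abs=1e-12)
        assert pcc_per_plane(-2.0 * a + 1, b, Plane.FRONTAL) == pytest.approx(-base, abs=1e-12)

    def test_plane_selects_coordinate_column(self, rng):
        y = np.linspace(0, 100, 30)
        spl = np.column_stack([np.sin(y / 10), y, np.cos(y / 15)])
        isl = np.column_stack([np.sin(y / 10), y, -np.cos(y / 15)])
        assert pcc_per_plane(spl, isl, "frontal") == 1.0
        assert pcc_per_plane(spl, isl, "sagittal") == -1.0

    def test_zero_variance_names_flat_curve(self):
        a = np.zeros(20)
        b = np.linspace(0, 1, 20)
        with pytest.raises(UndefinedCorrelationError, match="SPL"):
            pcc_per_plane(a, b, Plane.FRONTAL)


class TestPostureInvariance:
    def test_pcc_after_alignment_survives_rigid_pretransform(self, rng):
        """Shape correlation must not depend on posture offsets."""
        spl = smooth_curve(sine_polyline(amplitude=12)).points
        isl = smooth_curve(sine_polyline(amplitude=8, wavelength=350.0)).points
        aligned, _, _ = procrustes_align(spl, isl)
        base = pcc_per_plane(spl, aligned, Plane.FRONTAL)
        pre = RigidTransform(Rotation.random(random_state=21).as_matrix(), [40.0, 500.0, -3.0])
        aligned2, _, _ = procrustes_align(spl, pre.apply(isl))
        assert pcc_per_plane(spl, aligned2, Plane.FRONTAL) == pytest.approx(base, abs=1e-9)
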