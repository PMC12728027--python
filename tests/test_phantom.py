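"""Synthetic-patient generator: ground truth, determinism, noise model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinalign import pipeline
from spinalign.phantom import (
    PhantomSpec,
    _FrontalCurve,
    _SagittalCurve,
    generate_cohort,
    generate_phantom,
    random_postural_transform,
)
from spinalign.registration import fit_rigid, marker_rmse
from spinalign.types import CorrespondenceSet, RigidTransform, View

ALL_CFG = pipeline.PipelineConfig(marker_names="all")


def null_spec(**kwargs):
    return PhantomSpec(
        frontal_amplitude_mm=0.0,
        kyphosis_angle_deg=0.0,
        lordosis_angle_deg=0.0,
        skin_shift_coef=0.0,
        **kwargs,
    )


def rotation_error_deg(R_rec, R_true):
    return np.degrees(Rotation.from_matrix(R_rec @ R_true.T).magnitude())


class TestGeneratePhantom:
    def test_null_phantom_full_pipeline(self):
        result = pipeline.process_bundle(generate_phantom(null_spec()), ALL_CFG)
        assert result["correlation"]["pcc_frontal"] == 1.0
        assert result["correlation"]["pcc_sagittal"] == 1.0
        assert result["cobb"]["frontal_primary_deg"] == pytest.approx(0.0, abs=1e-6)
        assert result["cobb"]["kyphotic_deg"] == 0.0
        assert result["registration"]["marker_rmse_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_s_curve_cobb_within_1deg_of_truth(self):
        spec = PhantomSpec(frontal_amplitude_mm=10.0, frontal_wavelength_mm=400.0)
        bundle = generate_phantom(spec)
        result = pipeline.process_bundle(bundle, ALL_CFG)
        assert result["cobb"]["frontal_primary_deg"] == pytest.approx(
            bundle.truth.cobb_frontal_deg, abs=1.0
        )

    def test_noiseless_pipeline_recovers_postural_transform(self):
        T = random_postural_transform(np.random.default_rng(3))
        bundle = generate_phantom(PhantomSpec(postural_transform=T))
        result = pipeline.process_bundle(bundle, ALL_CFG)
        R_rec = np.array(result["registration"]["transform"]["rotation"])
        assert np.radians(rotation_error_deg(R_rec, T.rotation)) < 1e-6

    def test_noiseless_pcc_matches_construction_truth(self):
        bundle = generate_phantom(PhantomSpec(seed=11))
        result = pipeline.process_bundle(bundle, ALL_CFG)
        assert result["correlation"]["pcc_frontal"] == pytest.approx(
            bundle.truth.pcc_frontal, abs=0.01
        )
        assert result["correlation"]["pcc_sagittal"] == pytest.approx(
            bundle.truth.pcc_sagittal, abs=0.01
        )

    def test_same_seed_reproduces_identical_output(self):
        spec = PhantomSpec(marker_noise_sd_mm=2.0, surface_noise_sd_mm=1.0, seed=99)
        a, b = generate_phantom(spec), generate_phantom(spec)
        np.testing.assert_array_equal(a.scan.cloud, b.scan.cloud)
        for name in a.scan.markers:
            np.testing.assert_array_equal(a.scan.markers[name], b.scan.markers[name])
        for view in (View.FRONTAL, View.LATERAL):
            np.testing.assert_array_equal(
                a.annotations[view].isl_polyline, b.annotations[view].isl_polyline
            )

    def test_different_seeds_change_noise_realisation(self):
        kwargs = dict(marker_noise_sd_mm=2.0)
        a = generate_phantom(PhantomSpec(seed=1, **kwargs))
        b = generate_phantom(PhantomSpec(seed=2, **kwargs))
        assert not np.allclose(a.scan.markers["C7"], b.scan.markers["C7"])


class TestAnalyticTruth:
    @pytest.mark.parametrize(
        "spec",
        [
            PhantomSpec(frontal_amplitude_mm=10, frontal_wavelength_mm=400),
            PhantomSpec(frontal_amplitude_mm=25, curve_mode="arc"),
        ],
        ids=["sine", "arc"],
    )
    def test_frontal_truth_agrees_with_dense_differentiation(self, spec):
        """Closed-form Cobb vs central differences on the analytic curve."""
        fc = _FrontalCurve(spec)
        y = np.linspace(0, spec.spine_length_mm, 100_000)
        ang = np.degrees(np.arctan(np.gradient(fc.x(y), y)))
        assert fc.cobb_deg() == pytest.approx(ang.max() - ang.min(), abs=0.1)

    def test_sagittal_truth_slopes_match_prescribed_angles(self):
        spec = PhantomSpec(kyphosis_angle_deg=38.0, lordosis_angle_deg=52.0)
        sc = _SagittalCurve(spec)
        S, yT = spec.spine_length_mm, spec.junction_fraction * spec.spine_length_mm
        phi = lambda y: np.degrees(np.arctan(sc.dz(np.array([y]))[0]))
        assert phi(yT) - phi(S) == pytest.approx(38.0, abs=1e-9)
        assert phi(yT) - phi(0.0) == pytest.approx(52.0, abs=1e-9)

    def test_sagittal_curvature_changes_sign_only_at_junction(self):
        sc = _SagittalCurve(PhantomSpec())
        y = np.linspace(1.0, 449.0, 2000)
        d2 = np.gradient(sc.dz(y), y)
        signs = np.sign(d2[np.abs(d2) > 1e-8])
        assert np.sum(np.diff(signs) != 0) == 1


class TestNoiseScaling:
    def test_marker_rmse_scales_linearly_with_sigma(self):
        """Registration RMSE is proportional to the marker noise SD."""
        sigmas = [0.5, 1.0, 2.0, 4.0]
        medians = []
        for sigma in sigmas:
            rmses = []
            for rep in range(60):
                bundle = generate_phantom(
                    PhantomSpec(marker_noise_sd_mm=sigma, seed=1000 * rep + int(10 * sigma))
                )
                names = sorted(bundle.truth.markers_eos)
                corr = CorrespondenceSet(
                    names,
                    np.array([bundle.scan.markers[n] for n in names]),
                    np.array([bundle.truth.markers_eos[n] for n in names]),
                )
                rmse, _, _ = marker_rmse(fit_rigid(corr), corr)
                rmses.append(rmse)
            medians.append(np.median(rmses))
        ratio = np.array(medians) / np.array(sigmas)
        assert np.max(ratio) / np.min(ratio) < 1.15  # proportional within 15%
        slope, intercept = np.polyfit(sigmas, medians, 1)
        assert abs(intercept) < 0.15 * slope


class TestCohort:
    def test_cohort_median_frontal_cobb_matches_population(self):
        bundles = generate_cohort(30, seed=1234)
        med = np.median([b.truth.cobb_frontal_deg for b in bundles])
        assert 25.0 <= med <= 33.0

    def test_single_patient_cohort(self):
        (bundle,) = generate_cohort(1, seed=5)
        assert bundle.truth.cobb_frontal_deg > 0
        assert isinstance(bundle.truth.postural_transform, RigidTransform)

    def test_cohort_is_deterministic_under_seed(self):
        a = generate_cohort(3, seed=77)
        b = generate_cohort(3, seed=77)
        for pa, pb in zip(a, b):
            assert pa.spec.seed == pb.spec.seed
            assert pa.spec.frontal_amplitude_mm == pb.spec.frontal_amplitude_mm
            np.testing.assert_array_equal(
                pa.spec.postural_transform.rotation, pb.spec.postural_transform.rotation
            )
            np.testing.assert_array_equal(pa.scan.cloud, pb.scan.cloud)
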