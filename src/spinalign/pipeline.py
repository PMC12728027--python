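"""End-to-end patient processing and cohort aggregation.

One patient = two annotated radiographic views plus an annotated 3D
back-surface scan.  Processing runs the full chain: triangulate the
markers and the internal spine line from the biplanar annotations,
rigidly register the scanner frame onto the radiographic frame from
the named marker correspondences, transform the spinous process line,
smooth both lines, superimpose them by rotation+translation-only
Procrustes, compute the per-plane shape correlations, and derive the
frontal/kyphotic/lordotic Cobb angles from the smoothed internal line.

Batch results are deterministic: result files contain no wall-clock
content; per-stage timings are logged to the ``spinalign`` logger.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import biplanar, cobb, curves, io, registration
from .phantom import PhantomBundle
from .types import (
    CorrespondenceSet,
    Plane,
    SingleCurveError,
    SpinalignError,
    View,
)

__all__ = ["PipelineConfig", "process_patient", "process_bundle", "summarize_cohort", "run_batch"]

logger = logging.getLogger("spinalign")

#: The four-marker registration set of the manual clinical workflow.
DEFAULT_MARKERS = ("C7", "L5", "PSIS_L", "PSIS_R")


@dataclass
class PipelineConfig:
    """All pipeline tunables in one place.

    ``marker_names`` selects the registration markers: a tuple of names
    or ``"all"`` for every marker present in both modalities.  The
    four-marker default mirrors the manual workflow; automated batches
    (where marker picking costs nothing) can use all nine.
    """

    n_samples: int = 100
    smoothing: float | str = "auto"
    tangent_window_mm: float = cobb.DEFAULT_TANGENT_WINDOW_MM
    min_segment_mm: float = cobb.MIN_SEGMENT_MM
    marker_names: tuple[str, ...] | str = DEFAULT_MARKERS
    residual_warn_mm: float = biplanar.Y_RESIDUAL_WARN_MM
    seed: int = 0

    @classmethod
    def from_toml(cls, path: Path | str) -> "PipelineConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        kwargs = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if isinstance(kwargs.get("marker_names"), list):
            kwargs["marker_names"] = tuple(kwargs["marker_names"])
        return cls(**kwargs)


def _select_markers(
    radiographic: dict[str, np.ndarray],
    scanner: dict[str, np.ndarray],
    which: tuple[str, ...] | str,
) -> CorrespondenceSet:
    common = sorted(set(radiographic) & set(scanner))
    if which != "all":
        missing = [m for m in which if m not in common]
        if missing:
            raise SpinalignError(f"registration markers missing from data: {missing}")
        common = list(which)
    return CorrespondenceSet(
        names=common,
        source=np.array([scanner[m] for m in common]),
        target=np.array([radiographic[m] for m in common]),
    )


def _safe_pcc(spl_pts: np.ndarray, isl_pts: np.ndarray, plane: Plane) -> float:
    """PCC with the degenerate both-flat case mapped to perfect agreement.

    Flatness is judged at 1e-9 mm so that sequences that are straight up
    to floating-point noise do not yield a correlation of pure round-off.
    """
    i = plane.coord_index
    flat_spl = spl_pts[:, i].std() < 1e-9
    flat_isl = isl_pts[:, i].std() < 1e-9
    if flat_spl and flat_isl:
        return 1.0  # two straight lines: shapes agree exactly
    return curves.pcc_per_plane(spl_pts, isl_pts, plane)


def process_bundle(
    inputs: dict | PhantomBundle, config: PipelineConfig | None = None
) -> dict:
    """Run the full chain on in-memory inputs; returns the result dict.

    ``inputs`` is either a loaded patient folder
    (:func:`spinalign.io.load_patient_folder`) or a
    :class:`~spinalign.phantom.PhantomBundle`.
    """
    cfg = config or PipelineConfig()
    if isinstance(inputs, PhantomBundle):
        inputs = {
            "patient_id": f"phantom-{inputs.spec.seed}",
            "frame_frontal": inputs.frames[View.FRONTAL],
            "frame_lateral": inputs.frames[View.LATERAL],
            "annotation_frontal": inputs.annotations[View.FRONTAL],
            "annotation_lateral": inputs.annotations[View.LATERAL],
            "scan_markers": inputs.scan.markers,
            "spl_polyline": inputs.scan.spl_polyline,
            "cloud": inputs.scan.cloud,
        }
    t0 = time.perf_counter()
    notes: list[str] = []

    # 1. biplanar reconstruction
    markers3d, y_residuals = biplanar.reconstruct_markers(
        inputs["annotation_frontal"],
        inputs["frame_frontal"],
        inputs["annotation_lateral"],
        inputs["frame_lateral"],
        residual_warn_mm=cfg.residual_warn_mm,
    )
    isl3d = biplanar.reconstruct_isl(
        inputs["annotation_frontal"],
        inputs["frame_frontal"],
        inputs["annotation_lateral"],
        inputs["frame_lateral"],
        n_samples=cfg.n_samples,
    )
    t1 = time.perf_counter()

    # 2. rigid registration scanner -> radiographic frame
    corr = _select_markers(markers3d, inputs["scan_markers"], cfg.marker_names)
    transform = registration.fit_rigid(corr)
    rmse, per_marker, rmse_sd = registration.marker_rmse(transform, corr)
    spl3d = registration.apply_transform(transform, inputs["spl_polyline"])
    t2 = time.perf_counter()

    # 3. smoothing, Procrustes, per-plane correlation
    spl_curve = curves.smooth_curve(spl3d, cfg.smoothing, cfg.n_samples, "SPL")
    isl_curve = curves.smooth_curve(isl3d, cfg.smoothing, cfg.n_samples, "ISL")
    spl_c, isl_c = curves.resample_pair(spl_curve, isl_curve, cfg.n_samples)
    isl_aligned, disparity, _ = curves.procrustes_align(spl_c, isl_c)
    pcc_f = _safe_pcc(spl_c.points, isl_aligned, Plane.FRONTAL)
    pcc_s = _safe_pcc(spl_c.points, isl_aligned, Plane.SAGITTAL)
    t3 = time.perf_counter()

    # 4. Cobb angles from the smoothed internal line
    segments, primary = cobb.cobb_frontal(isl_curve, cfg.tangent_window_mm, cfg.min_segment_mm)
    try:
        kyph, lord = cobb.cobb_sagittal(isl_curve, cfg.tangent_window_mm, cfg.min_segment_mm)
        kyph_deg, lord_deg = kyph.angle_deg, lord.angle_deg
        sagittal_segments = [kyph.to_dict(), lord.to_dict()]
    except SingleCurveError:
        dense = isl_curve.spline_z.derivative(2)(isl_curve.y_grid)
        span = isl_curve.y_range[1] - isl_curve.y_range[0]
        if np.max(np.abs(dense)) * span**2 < 1e-6:
            kyph_deg = lord_deg = 0.0  # straight sagittal profile
            sagittal_segments = []
            notes.append("sagittal profile straight; kyphotic/lordotic set to 0")
        else:
            kyph_deg = lord_deg = None
            sagittal_segments = []
            notes.append("sagittal profile is a single curve; kyphotic/lordotic undefined")
    t4 = time.perf_counter()

    logger.info(
        "%s: triangulation %.0f ms, registration %.0f ms, correlation %.0f ms, cobb %.0f ms",
        inputs.get("patient_id", "?"),
        1e3 * (t1 - t0),
        1e3 * (t2 - t1),
        1e3 * (t3 - t2),
        1e3 * (t4 - t3),
    )

    return {
        "patient_id": inputs.get("patient_id", ""),
        "status": "processed",
        "registration": {
            "marker_names": corr.names,
            "marker_rmse_mm": rmse,
            "residual_sd_mm": rmse_sd,
            "per_marker_residuals_mm": per_marker,
            "transform": transform.to_dict(),
        },
        "triangulation": {"y_residuals_mm": y_residuals},
        "correlation": {
            "pcc_frontal": pcc_f,
            "pcc_sagittal": pcc_s,
            "procrustes_disparity": disparity,
            "n_common_samples": spl_c.n_samples,
        },
        "cobb": {
            "frontal_primary_deg": primary.angle_deg,
            "frontal_segments": [s.to_dict() for s in segments],
            "kyphotic_deg": kyph_deg,
            "lordotic_deg": lord_deg,
            "sagittal_segments": sagittal_segments,
        },
        "notes": notes,
    }


def process_patient(
    folder: Path | str, config: PipelineConfig | None = None, write_result: bool = True
) -> dict:
    """Process one patient folder; on any stage error the result records
    ``status: failed`` with the stage message instead of raising."""
    folder = Path(folder)
    try:
        inputs = io.load_patient_folder(folder)
        result = process_bundle(inputs, config)
    except (SpinalignError, FileNotFoundError, ValueError) as exc:
        logger.warning("%s failed: %s", folder.name, exc)
        result = {"patient_id": folder.name, "status": "failed", "error": str(exc)}
    if write_result:
        io.write_json(folder / "result.json", result)
    return result


def run_batch(
    root: Path | str, config: PipelineConfig | None = None, write_results: bool = True
) -> list[dict]:
    """Process every patient subfolder of ``root`` (sorted by name)."""
    root = Path(root)
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise SpinalignError(f"no patient folders under {root}")
    return [process_patient(f, config, write_results) for f in folders]


def _median_iqr(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])  # linear-interpolation quantiles
    return {"median": float(np.median(arr)), "iqr": float(q3 - q1), "n": len(arr)}


def summarize_cohort(results: list[dict]) -> dict:
    """Aggregate processed patients into cohort medians and IQRs.

    Failed patients are excluded and counted.  Metrics: marker RMSE and
    residual SD (per patient, and per-marker pooled), per-plane PCC,
    and the three Cobb angles.  Raises on an empty processed set.
    """
    processed = [r for r in results if r.get("status") == "processed"]
    failed = [r for r in results if r.get("status") != "processed"]
    if not processed:
        raise SpinalignError("no successfully processed patients to summarize")

    def collect(path: tuple[str, str]) -> list[float]:
        sec, key = path
        return [r[sec][key] for r in processed if r[sec][key] is not None]

    pooled_residuals = [
        v for r in processed for v in r["registration"]["per_marker_residuals_mm"].values()
    ]
    summary = {
        "n_processed": len(processed),
        "n_failed": len(failed),
        "failed_patients": sorted(r.get("patient_id", "?") for r in failed),
        "marker_rmse_mm": _median_iqr(collect(("registration", "marker_rmse_mm"))),
        "residual_sd_mm": _median_iqr(collect(("registration", "residual_sd_mm"))),
        "per_marker_residual_mm": _median_iqr(pooled_residuals),
        "pcc_frontal": _median_iqr(collect(("correlation", "pcc_frontal"))),
        "pcc_sagittal": _median_iqr(collect(("correlation", "pcc_sagittal"))),
        "cobb_frontal_primary_deg": _median_iqr(collect(("cobb", "frontal_primary_deg"))),
    }
    for key in ("kyphotic_deg", "lordotic_deg"):
        vals = collect(("cobb", key))
        summary[f"cobb_{key}"] = _median_iqr(vals) if vals else None
    return summary
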