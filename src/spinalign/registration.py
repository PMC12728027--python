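"""Marker-based rigid registration of scanner and radiographic frames.

The back-surface scan lives in the 3D scanner's coordinate system; the
triangulated radiographic markers live in the shared biplanar (EOS)
frame.  Because the same physical skin markers are observed in both
modalities, the least-squares proper rigid transform between the two
named point sets registers the scan into the radiographic frame.  The
closed-form solution (Kabsch): translate both sets to their centroids,
take the SVD of the cross-covariance, and correct an improper optimum
by flipping the sign of the smallest singular direction.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt

from .types import CorrespondenceSet, DegenerateGeometryError, RigidTransform

__all__ = ["fit_rigid", "apply_transform", "marker_rmse", "COLLINEARITY_RTOL"]

#: Source geometry is rejected as collinear when the second-smallest
#: singular value of the centred source matrix falls below this
#: fraction of the largest.
COLLINEARITY_RTOL = 1e-6


def fit_rigid(correspondences: CorrespondenceSet) -> RigidTransform:
    """Least-squares proper rigid fit of source onto target markers.

    Minimises ``sum_i || R s_i + t - g_i ||^2`` over proper rotations R
    and translations t, with uniform weights.  Requires at least three
    non-collinear source points; degenerate geometry raises
    :class:`DegenerateGeometryError`.
    """
    src = correspondences.source
    tgt = correspondences.target
    if len(src) < 3:
        raise DegenerateGeometryError(
            f"rigid fit needs >= 3 correspondences, got {len(src)}"
        )
    src_c = src - src.mean(axis=0)
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < COLLINEARITY_RTOL * sv[0]:
        raise DegenerateGeometryError(
            "source markers are (near-)collinear; rotation is not identifiable"
        )
    tgt_c = tgt - tgt.mean(axis=0)
    H = src_c.T @ tgt_c  # cross-covariance
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # rank-deficient cross-covariance; pick the proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def apply_transform(
    t: RigidTransform, points: npt.NDArray[np.float64]
) -> np.ndarray:
    """Apply ``p -> R p + t`` elementwise to a point, polyline or cloud."""
    return t.apply(points)


def marker_rmse(
    t: RigidTransform, correspondences: CorrespondenceSet
) -> tuple[float, dict[str, float], float]:
    """Post-registration marker discrepancy.

    Returns ``(rmse, per_marker, sd)`` where ``rmse`` is the root mean
    square of the Euclidean residuals ``|| R s_i + t - g_i ||``,
    ``per_marker`` maps marker names to their residual magnitudes (mm)
    and ``sd`` is the population standard deviation of those
    magnitudes.  This is the quality metric reported per patient after
    registration.
    """
    residuals = np.linalg.norm(
        t.apply(correspondences.source) - correspondences.target, axis=1
    )
    rmse = float(np.sqrt(np.mean(residuals**2)))
    sd = float(np.std(residuals))
    per_marker = {name: float(r) for name, r in zip(correspondences.names, residuals)}
    return rmse, per_marker, sd
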