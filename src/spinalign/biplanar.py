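"""Biplanar radiograph geometry: pixel calibration and 3D reconstruction.

A biplanar acquisition produces two simultaneous, mutually orthogonal
projections of the standing patient: a frontal image of the (x, y)
plane and a lateral image of the (z, y) plane of the shared frame.
Under the orthogonal-projection model each 2D annotation constrains two
of the three coordinates, so a marker picked in both views is
reconstructed by intersecting its two projection lines, and a drawn
spine line is reconstructed by fusing the two planar polylines over
their common vertical range.
"""

from __future__ import annotations

import warnings

import numpy as np
import numpy.typing as npt

from .types import (
    Annotation2D,
    EmptyOverlapError,
    NonMonotoneError,
    OutOfBoundsError,
    RadiographFrame,
    View,
)

__all__ = [
    "pixel_to_mm",
    "mm_to_pixel",
    "project_to_views",
    "triangulate_marker",
    "triangulate_polyline",
    "preprocess_polyline",
    "annotation_to_mm",
    "Y_RESIDUAL_WARN_MM",
]

#: Default threshold above which a marker's inter-view vertical
#: discrepancy is flagged (warning, not failure).
Y_RESIDUAL_WARN_MM = 15.0


def pixel_to_mm(
    p_px: npt.NDArray[np.float64] | tuple[float, float],
    frame: RadiographFrame,
) -> np.ndarray:
    """Convert pixel coordinates ``(col, row)`` to in-plane mm ``(u, y)``.

    ``u`` is the horizontal in-plane coordinate of the view (x for
    frontal, z for lateral) and ``y`` the vertical coordinate of the
    shared frame.  Rows are flipped so that y increases cranially:

        u = origin_u + spacing_col * col
        y = origin_y + spacing_row * (rows - 1 - row)

    Accepts a single ``(2,)`` point or an ``(n, 2)`` stack.  Raises
    :class:`OutOfBoundsError` for pixels outside the image.
    """
    p = np.asarray(p_px, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    rows, cols = frame.image_size_px
    col, row = p[:, 0], p[:, 1]
    if (col < 0).any() or (col > cols - 1).any() or (row < 0).any() or (row > rows - 1).any():
        raise OutOfBoundsError(
            f"pixel outside frame {frame.frame_id or frame.view.value} "
            f"of size {rows}x{cols}"
        )
    s_row, s_col = frame.pixel_spacing
    ou, oy = frame.origin_plane_mm
    out = np.column_stack([ou + s_col * col, oy + s_row * (rows - 1 - row)])
    return out[0] if single else out


def mm_to_pixel(
    p_mm: npt.NDArray[np.float64] | tuple[float, float],
    frame: RadiographFrame,
) -> np.ndarray:
    """Exact inverse of :func:`pixel_to_mm` (returns float pixels)."""
    p = np.asarray(p_mm, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    s_row, s_col = frame.pixel_spacing
    ou, oy = frame.origin_plane_mm
    rows, _ = frame.image_size_px
    col = (p[:, 0] - ou) / s_col
    row = rows - 1 - (p[:, 1] - oy) / s_row
    out = np.column_stack([col, row])
    return out[0] if single else out


def project_to_views(p: npt.NDArray[np.float64]) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonally project 3D point(s) into the two view planes.

    Returns ``(frontal, lateral)`` where frontal = (x, y) and
    lateral = (z, y).  Exact inverse of :func:`triangulate_marker`.
    """
    q = np.asarray(p, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    frontal = q[:, [0, 1]].copy()
    lateral = q[:, [2, 1]].copy()
    if single:
        return frontal[0], lateral[0]
    return frontal, lateral


def triangulate_marker(
    p_frontal: npt.NDArray[np.float64] | tuple[float, float],
    p_lateral: npt.NDArray[np.float64] | tuple[float, float],
    residual_warn_mm: float = Y_RESIDUAL_WARN_MM,
) -> tuple[np.ndarray, float, bool]:
    """Intersect the two orthogonal projections of one marker.

    x is taken from the frontal observation, z from the lateral one,
    and the two independent vertical observations are reconciled by
    their arithmetic mean.  Returns ``(point3, y_residual, flagged)``
    where ``y_residual = |y_frontal - y_lateral|`` is a per-marker
    quality metric and ``flagged`` is True when it exceeds
    ``residual_warn_mm`` (a warning is also emitted; this is never a
    hard failure).
    """
    pf = np.asarray(p_frontal, dtype=float).reshape(2)
    pl = np.asarray(p_lateral, dtype=float).reshape(2)
    y = 0.5 * (pf[1] + pl[1])
    residual = float(abs(pf[1] - pl[1]))
    flagged = residual > residual_warn_mm
    if flagged:
        warnings.warn(
            f"marker y-residual {residual:.1f} mm exceeds {residual_warn_mm:.1f} mm",
            stacklevel=2,
        )
    return np.array([pf[0], y, pl[0]]), residual, flagged


def preprocess_polyline(
    line_mm: npt.NDArray[np.float64],
    max_reordered_fraction: float = 0.05,
) -> np.ndarray:
    """Make a hand-drawn planar polyline strictly monotone in y.

    Drawn lines can locally backtrack vertically.  Points are sorted by
    y (stable) and duplicate y values collapsed by averaging the
    horizontal coordinate.  If more than ``max_reordered_fraction`` of
    the points had to move during sorting the drawing is rejected with
    :class:`NonMonotoneError`.

    Input/output columns are ``(u, y)``; output y is strictly increasing.
    """
    pts = np.asarray(line_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise NonMonotoneError("polyline must be an (n>=2, 2) array of (u, y)")
    order = np.argsort(pts[:, 1], kind="stable")
    n_moved = int(np.sum(order != np.arange(len(pts))))
    # the line may legitimately be drawn top-down (C7 -> L5): a full
    # reversal is not a defect, so compare against the better direction
    order_rev = np.argsort(pts[::-1, 1], kind="stable")
    n_moved_rev = int(np.sum(order_rev != np.arange(len(pts))))
    n_moved = min(n_moved, n_moved_rev)
    if n_moved > max_reordered_fraction * len(pts):
        raise NonMonotoneError(
            f"{n_moved}/{len(pts)} polyline points reordered in y "
            f"(> {max_reordered_fraction:.0%}); drawing rejected"
        )
    pts = pts[order]
    y, u = pts[:, 1], pts[:, 0]
    uniq_y, inverse = np.unique(y, return_inverse=True)
    if len(uniq_y) < len(y):
        u = np.bincount(inverse, weights=u) / np.bincount(inverse)
        y = uniq_y
    if len(y) < 2:
        raise NonMonotoneError("polyline collapses to fewer than 2 distinct y values")
    return np.column_stack([u, y])


def triangulate_polyline(
    line_frontal_mm: npt.NDArray[np.float64],
    line_lateral_mm: npt.NDArray[np.float64],
    n_samples: int = 100,
) -> np.ndarray:
    """Fuse two planar polylines into a 3D polyline.

    Both lines are parameterised by y over the intersection of their
    vertical ranges; x(y) is linearly interpolated from the frontal
    line, z(y) from the lateral line, and the fused curve is sampled at
    ``n_samples`` evenly spaced y values.  Returns an ``(n_samples, 3)``
    array with strictly increasing y spanning exactly the y-overlap.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    lf = preprocess_polyline(line_frontal_mm)
    ll = preprocess_polyline(line_lateral_mm)
    y_lo = max(lf[0, 1], ll[0, 1])
    y_hi = min(lf[-1, 1], ll[-1, 1])
    if y_hi <= y_lo:
        raise EmptyOverlapError(
            f"polylines share no y-range (frontal [{lf[0, 1]:.1f}, {lf[-1, 1]:.1f}], "
            f"lateral [{ll[0, 1]:.1f}, {ll[-1, 1]:.1f}])"
        )
    y = np.linspace(y_lo, y_hi, n_samples)
    x = np.interp(y, lf[:, 1], lf[:, 0])
    z = np.interp(y, ll[:, 1], ll[:, 0])
    return np.column_stack([x, y, z])


def annotation_to_mm(
    ann: Annotation2D, frame: RadiographFrame
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Convert one view's annotation from pixels to in-plane mm.

    Returns ``(markers_mm, polyline_mm)`` with every entry as (u, y).
    Validates pixel bounds first.
    """
    ann.validate_against(frame)
    markers = {name: pixel_to_mm(np.asarray(p), frame) for name, p in ann.markers.items()}
    poly = pixel_to_mm(ann.isl_polyline, frame)
    return markers, poly


def reconstruct_markers(
    ann_frontal: Annotation2D,
    frame_frontal: RadiographFrame,
    ann_lateral: Annotation2D,
    frame_lateral: RadiographFrame,
    residual_warn_mm: float = Y_RESIDUAL_WARN_MM,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Triangulate every marker named in both views.

    Returns ``(markers3d, y_residuals)`` keyed by marker name, sorted
    by name for determinism.
    """
    if frame_frontal.view is not View.FRONTAL or frame_lateral.view is not View.LATERAL:
        raise ValueError("frames must be passed as (frontal, lateral)")
    mf, _ = annotation_to_mm(ann_frontal, frame_frontal)
    ml, _ = annotation_to_mm(ann_lateral, frame_lateral)
    markers3d: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    for name in sorted(set(mf) & set(ml)):
        p3, res, _ = triangulate_marker(mf[name], ml[name], residual_warn_mm)
        markers3d[name] = p3
        residuals[name] = res
    return markers3d, residuals


def reconstruct_isl(
    ann_frontal: Annotation2D,
    frame_frontal: RadiographFrame,
    ann_lateral: Annotation2D,
    frame_lateral: RadiographFrame,
    n_samples: int = 100,
) -> np.ndarray:
    """Triangulate the drawn spine line (ISL) from both views into 3D."""
    _, pf = annotation_to_mm(ann_frontal, frame_frontal)
    _, pl = annotation_to_mm(ann_lateral, frame_lateral)
    return triangulate_polyline(pf, pl, n_samples=n_samples)
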