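"""Spinal-curve modelling: smoothing splines, Procrustes, correlation.

The two lines of interest are the spinous process line (SPL), drawn on
the back surface, and the internal spinal alignment (ISL), the line
through the vertebral body centroids reconstructed from the biplanar
radiographs.  Each is modelled as a pair of penalized smoothing splines
x(y), z(y) over the vertical coordinate and resampled on a regular y
grid.  Shape similarity is quantified per anatomical plane by the
Pearson correlation of the paired coordinate sequences after a
rotation+translation-only (no scaling) Procrustes superimposition of
the ISL onto the SPL, which makes the statistic invariant to the
postural offset between acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from .types import (
    EmptyOverlapError,
    Plane,
    RigidTransform,
    SpinalignError,
    UndefinedCorrelationError,
)

__all__ = [
    "SpineCurve",
    "smooth_curve",
    "resample_pair",
    "procrustes_align",
    "pcc_per_plane",
]


@dataclass
class SpineCurve:
    """A smoothed, regularly resampled 3D spinal line.

    ``spline_x`` and ``spline_z`` model the frontal and sagittal
    deviations as functions of the vertical coordinate y.  ``y_grid``
    holds n >= 10 equally spaced, strictly increasing sample positions;
    ``points`` always evaluates the stored splines on that grid.
    """

    source_label: str  # "SPL" | "ISL"
    spline_x: BSpline
    spline_z: BSpline
    y_grid: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        y = np.asarray(self.y_grid, dtype=float)
        if len(y) < 10:
            raise SpinalignError("SpineCurve needs a sample grid of >= 10 points")
        dy = np.diff(y)
        if (dy <= 0).any() or not np.allclose(dy, dy[0], rtol=1e-8):
            raise SpinalignError("y_grid must be strictly increasing and equally spaced")
        self.y_grid = y

    @property
    def n_samples(self) -> int:
        return len(self.y_grid)

    @property
    def y_range(self) -> tuple[float, float]:
        return float(self.y_grid[0]), float(self.y_grid[-1])

    @property
    def points(self) -> np.ndarray:
        """Sampled (n, 3) points (x, y, z) on the stored grid."""
        return self.evaluate(self.y_grid)

    def evaluate(self, y: npt.NDArray[np.float64]) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.column_stack([self.spline_x(y), y, self.spline_z(y)])

    def coord_spline(self, plane: Plane) -> BSpline:
        return self.spline_x if plane is Plane.FRONTAL else self.spline_z

    def resampled(self, y_lo: float, y_hi: float, n: int) -> "SpineCurve":
        """Same splines on a new regular grid over [y_lo, y_hi]."""
        return SpineCurve(
            self.source_label, self.spline_x, self.spline_z, np.linspace(y_lo, y_hi, n)
        )


def _fit_1d(y: np.ndarray, v: np.ndarray, smoothing: float | str) -> BSpline:
    if isinstance(smoothing, str):
        if smoothing != "auto":
            raise ValueError(f"smoothing must be a number or 'auto', got {smoothing!r}")
        lam = None  # generalized cross-validation
    else:
        lam = float(smoothing)
    if len(y) < 5:
        # the GCV smoother needs 5 points; an exact cubic interpolant is
        # the natural zero-penalty limit for the minimal 4-point input
        return make_interp_spline(y, v, k=3)
    return make_smoothing_spline(y, v, lam=lam)


def smooth_curve(
    line: npt.NDArray[np.float64],
    smoothing: float | str = "auto",
    n_samples: int = 100,
    source_label: str = "ISL",
) -> SpineCurve:
    """Fit penalized smoothing splines x(y), z(y) to a 3D polyline.

    ``smoothing`` is the roughness-penalty weight; ``"auto"`` selects
    it per coordinate by generalized cross-validation.  Straight lines
    lie in the null space of the penalty and are reproduced exactly for
    any penalty.  The curve is resampled at ``n_samples`` regular y
    intervals spanning the input's y range.

    The input must have at least 4 points and weakly monotone y
    (duplicate y values are collapsed by averaging).
    """
    pts = np.asarray(line, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise SpinalignError("expected an (n, 3) polyline")
    if len(pts) < 4:
        raise SpinalignError(f"smoothing needs >= 4 points, got {len(pts)}")
    order = np.argsort(pts[:, 1], kind="stable")
    pts = pts[order]
    y, inverse = np.unique(pts[:, 1], return_inverse=True)
    if len(y) < len(pts):
        counts = np.bincount(inverse)
        x = np.bincount(inverse, weights=pts[:, 0]) / counts
        z = np.bincount(inverse, weights=pts[:, 2]) / counts
    else:
        x, z = pts[:, 0], pts[:, 2]
    if len(y) < 4:
        raise SpinalignError("fewer than 4 distinct y values after preprocessing")
    sx = _fit_1d(y, x, smoothing)
    sz = _fit_1d(y, z, smoothing)
    grid = np.linspace(y[0], y[-1], n_samples)
    return SpineCurve(source_label, sx, sz, grid)


def resample_pair(
    a: SpineCurve, b: SpineCurve, n_samples: int | None = None
) -> tuple[SpineCurve, SpineCurve]:
    """Resample two curves onto a common regular grid over their y-overlap.

    The SPL spans skin landmarks and the ISL vertebral landmarks, so
    their y ranges generally differ; pairing restricts both to the
    intersection.
    """
    lo = max(a.y_range[0], b.y_range[0])
    hi = min(a.y_range[1], b.y_range[1])
    if hi <= lo:
        raise EmptyOverlapError("curves share no y-range")
    n = n_samples or max(a.n_samples, b.n_samples)
    return a.resampled(lo, hi, n), b.resampled(lo, hi, n)


def procrustes_align(
    reference: npt.NDArray[np.float64] | SpineCurve,
    moving: npt.NDArray[np.float64] | SpineCurve,
) -> tuple[np.ndarray, float, RigidTransform]:
    """Rotation+translation-only Procrustes superimposition.

    Centres both point sets, finds the proper 3D rotation minimising
    the summed squared distances (SVD of the cross-covariance) and maps
    the moving set onto the reference; the scale factor is fixed at 1,
    so the centroid size of the moving set is preserved exactly.

    Returns ``(aligned_moving, disparity, transform)`` where
    ``disparity`` is the summed squared residual after alignment.
    """
    ref = reference.points if isinstance(reference, SpineCurve) else np.asarray(reference, float)
    mov = moving.points if isinstance(moving, SpineCurve) else np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise SpinalignError(
            f"point sets must share a sample count, got {mov.shape} vs {ref.shape}"
        )
    mu_r = ref.mean(axis=0)
    mu_m = mov.mean(axis=0)
    H = (mov - mu_m).T @ (ref - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_r - R @ mu_m
    transform = RigidTransform(R, t)
    aligned = transform.apply(mov)
    disparity = float(np.sum((aligned - ref) ** 2))
    return aligned, disparity, transform


def pcc_per_plane(
    spl: npt.NDArray[np.float64],
    isl: npt.NDArray[np.float64],
    plane: Plane | str,
) -> float:
    """Pearson correlation of SPL and ISL in one anatomical plane.

        PCC = 1/(N-1) * sum_i ((SPL_i - mu_SPL)/sigma_SPL)
                             * ((ISL_i - mu_ISL)/sigma_ISL)

    where the sequences are the in-plane horizontal coordinates of the
    commonly sampled, Procrustes-aligned curves (x for the frontal
    plane, z for the sagittal plane), each centred by its own mean, and
    the sigmas are sample standard deviations (N-1 denominator).

    Accepts (n, 3) point arrays or already-extracted 1D sequences.
    Raises :class:`UndefinedCorrelationError` if either sequence has
    zero variance.
    """
    plane = Plane(plane)
    a = np.asarray(spl, dtype=float)
    b = np.asarray(isl, dtype=float)
    if a.ndim == 2:
        a = a[:, plane.coord_index]
    if b.ndim == 2:
        b = b[:, plane.coord_index]
    if a.shape != b.shape or a.ndim != 1:
        raise SpinalignError("sequences must be 1D and equally long")
    n = len(a)
    if n < 3:
        raise SpinalignError("PCC needs at least 3 samples")
    sa = a.std(ddof=1)
    sb = b.std(ddof=1)
    if sa == 0.0 or sb == 0.0:
        flat = "SPL" if sa == 0.0 else "ISL"
        raise UndefinedCorrelationError(
            f"{flat} {plane.value}-plane sequence has zero variance; PCC undefined"
        )
    # exact limits, free of floating-point round-off
    if np.array_equal(a, b):
        return 1.0
    if np.array_equal(a, -b):
        return -1.0
    pcc = float(np.sum((a - a.mean()) / sa * (b - b.mean()) / sb) / (n - 1))
    # guard against rounding just past the theoretical bounds
    return min(1.0, max(-1.0, pcc))
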