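"""Cobb angles from smoothed spinal lines.

The clinical Cobb angle of a spinal curve is the angle between the two
most-tilted vertebral endplates.  On a smoothed centreline the
most-tilted locations of each curve segment are the curvature
inflection points (where the second derivative of the in-plane
coordinate changes sign), with the curve endpoints serving as boundary
anchors so that single (C-shaped) and double (S-shaped) curves both
yield angles.  Tangent slopes at those locations are estimated by a
local ordinary-least-squares line fit, and the Cobb angle of a segment
is ``|atan(s_upper) - atan(s_lower)|`` in degrees.

Sagittal convention: the z axis points posteriorly, so a kyphotic
(posteriorly convex, thoracic) segment has z'' < 0 and a lordotic
(anteriorly convex, lumbar) segment z'' > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy.optimize import brentq
from scipy.stats import pearsonr

from .curves import SpineCurve
from .types import CobbMeasurement, Plane, SingleCurveError, SpinalignError

__all__ = [
    "InflectionSet",
    "find_inflections",
    "local_tangent",
    "cobb_segments",
    "cobb_frontal",
    "cobb_sagittal",
    "compare_cobb",
    "DEFAULT_TANGENT_WINDOW_MM",
    "MIN_SEGMENT_MM",
]

#: Half-width*2 of the local tangent regression (mm), about one
#: vertebral height; small enough that the OLS slope bias stays well
#: under 1 degree even on tight curves (amplitude/length ratio 0.1).
DEFAULT_TANGENT_WINDOW_MM = 20.0

#: Interior inflections closer than this are merged (mm).
MIN_SEGMENT_MM = 20.0

# second-derivative magnitudes below this fraction of the curve-wide
# maximum are treated as zero (suppresses spurious sign changes of a
# numerically straight spline)
_CURVATURE_RTOL = 1e-7


@dataclass
class InflectionSet:
    """Interior curvature inflections plus the curve endpoints.

    ``interior`` holds the y positions (strictly increasing) where the
    second derivative of the plane coordinate changes sign; ``lower``
    and ``upper`` are the curve's y endpoints used as boundary anchors.
    """

    interior: npt.NDArray[np.float64]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.interior, dtype=float)
        if arr.size and ((np.diff(arr) <= 0).any() or arr[0] <= self.lower or arr[-1] >= self.upper):
            raise SpinalignError("interior inflections must be strictly increasing inside range")
        self.interior = arr

    @property
    def breaks(self) -> np.ndarray:
        """All segment boundaries: lower endpoint, inflections, upper endpoint."""
        return np.concatenate([[self.lower], self.interior, [self.upper]])


def find_inflections(
    curve: SpineCurve,
    plane: Plane | str,
    min_segment_mm: float = MIN_SEGMENT_MM,
) -> InflectionSet:
    """Locate curvature inflections of the plane coordinate.

    Evaluates the spline's second derivative on the sample grid, finds
    sign changes, refines each by bisection, and merges inflections
    closer than ``min_segment_mm`` (to their midpoint; inflections that
    close to an endpoint are dropped).  A straight curve yields an
    empty interior set.
    """
    plane = Plane(plane)
    if curve.n_samples < 10:
        raise SpinalignError("inflection search needs a curve with >= 10 samples")
    d2 = curve.coord_spline(plane).derivative(2)
    y = curve.y_grid
    v = d2(y)
    scale = np.max(np.abs(v))
    lo, hi = curve.y_range
    span = hi - lo
    if scale * span**2 < 1e-9:  # numerically straight
        return InflectionSet(np.array([]), lo, hi)
    v = np.where(np.abs(v) < _CURVATURE_RTOL * scale, 0.0, v)
    roots: list[float] = []
    sign = np.sign(v)
    # skip exact zeros when looking for a sign change
    nz = np.nonzero(sign)[0]
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] < 0:
            roots.append(float(brentq(d2, y[a], y[b], xtol=1e-8)))
    roots_arr = np.array(sorted(roots))
    # merge close inflections, then drop any hugging an endpoint
    merged: list[float] = []
    for r in roots_arr:
        if merged and r - merged[-1] < min_segment_mm:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    interior = np.array([r for r in merged if r - lo >= min_segment_mm and hi - r >= min_segment_mm])
    return InflectionSet(interior, lo, hi)


def _local_slope(
    curve: SpineCurve, plane: Plane, y0: float, window_mm: float, order: int
) -> float:
    lo, hi = curve.y_range
    if not (lo <= y0 <= hi):
        raise SpinalignError(f"y0={y0:.1f} outside curve range [{lo:.1f}, {hi:.1f}]")
    y = curve.y_grid
    v = curve.coord_spline(plane)(y)
    w = float(window_mm)
    span = hi - lo
    if w > span:
        warnings.warn(
            "tangent window exceeds curve span; falling back to a global fit",
            stacklevel=3,
        )
        mask = np.ones_like(y, dtype=bool)
    else:
        while True:
            mask = np.abs(y - y0) <= w / 2
            if mask.sum() >= 5:
                break
            w *= 1.5
            if w > span:
                warnings.warn(
                    "tangent window exceeds curve span; falling back to a global fit",
                    stacklevel=3,
                )
                mask = np.ones_like(y, dtype=bool)
                break
    yy, vv = y[mask], v[mask]
    if order == 1:
        yc = yy - yy.mean()
        return float((yc @ (vv - vv.mean())) / (yc @ yc))
    # polynomial fit about y0; the linear coefficient is the slope at y0
    coeffs = np.polynomial.polynomial.polyfit(yy - y0, vv, order)
    return float(coeffs[1])


def local_tangent(
    curve: SpineCurve,
    plane: Plane | str,
    y0: float,
    window_mm: float = DEFAULT_TANGENT_WINDOW_MM,
) -> float:
    """Tangent slope d(coord)/dy at y0 by local linear regression.

    Fits an ordinary-least-squares line to the curve samples with
    ``|y - y0| <= window/2``; the window is widened by 50% steps until
    it holds at least 5 samples.  If the window grows beyond the whole
    curve an OLS fit over all samples is returned with a warning.

    A symmetric-window linear fit is unbiased at curvature inflections
    (the second derivative vanishes there), which is where the Cobb
    tangents are evaluated.  At the curve *endpoints* the window is
    one-sided and curvature generally does not vanish, so segment
    measurement uses a local quadratic fit there instead (see
    :func:`cobb_segments`).
    """
    return _local_slope(curve, Plane(plane), y0, window_mm, order=1)


def _measure_segment(
    curve: SpineCurve,
    plane: Plane,
    y_lo: float,
    y_hi: float,
    window_mm: float,
    curve_type: str,
) -> CobbMeasurement:
    lo, hi = curve.y_range
    # boundary anchors get a quadratic fit: the one-sided window there
    # would otherwise bias the slope by the (non-vanishing) curvature
    order_lo = 2 if np.isclose(y_lo, lo) else 1
    order_hi = 2 if np.isclose(y_hi, hi) else 1
    s_lo = _local_slope(curve, plane, y_lo, window_mm, order_lo)
    s_hi = _local_slope(curve, plane, y_hi, window_mm, order_hi)
    angle = float(abs(np.degrees(np.arctan(s_hi) - np.arctan(s_lo))))
    return CobbMeasurement(
        plane=plane,
        curve_type=curve_type,
        angle_deg=angle,
        lower_y=float(y_lo),
        upper_y=float(y_hi),
        slope_lower=s_lo,
        slope_upper=s_hi,
        direction=int(np.sign(s_hi - s_lo)),
    )


def cobb_segments(
    curve: SpineCurve,
    plane: Plane | str,
    window_mm: float = DEFAULT_TANGENT_WINDOW_MM,
    min_segment_mm: float = MIN_SEGMENT_MM,
) -> list[CobbMeasurement]:
    """Cobb angle of every segment between consecutive inflection/boundary points."""
    plane = Plane(plane)
    infl = find_inflections(curve, plane, min_segment_mm)
    breaks = infl.breaks
    label = "frontal_scoliotic" if plane is Plane.FRONTAL else "segment"
    return [
        _measure_segment(curve, plane, a, b, window_mm, label)
        for a, b in zip(breaks[:-1], breaks[1:])
    ]


def cobb_frontal(
    curve: SpineCurve,
    window_mm: float = DEFAULT_TANGENT_WINDOW_MM,
    min_segment_mm: float = MIN_SEGMENT_MM,
) -> tuple[list[CobbMeasurement], CobbMeasurement]:
    """Frontal (scoliotic) Cobb angles.

    Returns ``(segments, primary)`` where ``primary`` is the
    largest-angle segment, the clinical primary curve.
    """
    segments = cobb_segments(curve, Plane.FRONTAL, window_mm, min_segment_mm)
    primary = max(segments, key=lambda m: m.angle_deg)
    return segments, primary


def cobb_sagittal(
    curve: SpineCurve,
    window_mm: float = DEFAULT_TANGENT_WINDOW_MM,
    min_segment_mm: float = MIN_SEGMENT_MM,
) -> tuple[CobbMeasurement, CobbMeasurement]:
    """Kyphotic and lordotic Cobb angles from the sagittal profile.

    Expects the physiological double curve: one interior inflection
    separating a cranial kyphotic segment (z'' < 0, posteriorly
    convex) from a caudal lordotic one (z'' > 0).  With more than one
    interior inflection the two largest-angle segments are used with a
    warning; a profile with no interior inflection raises
    :class:`SingleCurveError`.
    """
    segments = cobb_segments(curve, Plane.SAGITTAL, window_mm, min_segment_mm)
    if len(segments) < 2:
        raise SingleCurveError(
            "sagittal profile has no interior curvature inflection "
            "(single curve); kyphotic/lordotic angles are undefined"
        )
    if len(segments) > 2:
        warnings.warn(
            f"sagittal profile has {len(segments) - 1} interior inflections; "
            "using the two largest-angle segments",
            stacklevel=2,
        )
        segments = sorted(segments, key=lambda m: -m.angle_deg)[:2]
        segments = sorted(segments, key=lambda m: m.lower_y)
    d2 = curve.spline_z.derivative(2)
    kyph = lord = None
    for seg in segments:
        mid = 0.5 * (seg.lower_y + seg.upper_y)
        seg.curve_type = "kyphotic" if d2(mid) < 0 else "lordotic"
        if seg.curve_type == "kyphotic":
            kyph = seg
        else:
            lord = seg
    if kyph is None or lord is None:
        # both segments bend the same way; label by position
        caudal, cranial = segments
        cranial.curve_type, caudal.curve_type = "kyphotic", "lordotic"
        warnings.warn("sagittal segments share convexity; labelled by position", stacklevel=2)
        kyph, lord = cranial, caudal
    return kyph, lord


def compare_cobb(
    measured: npt.NDArray[np.float64] | list[float],
    reference: npt.NDArray[np.float64] | list[float],
) -> dict:
    """Paired comparison of measured Cobb angles against a reference rater.

    Returns pairwise differences (measured - reference) with their
    median and IQR (linear-interpolation quantiles), and the Pearson
    correlation with a 95% confidence interval by the Fisher
    z-transformation.  Requires at least 3 pairs.
    """
    a = np.asarray(measured, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SpinalignError("paired angle lists must be 1D and equally long")
    n = len(a)
    if n < 3:
        raise SpinalignError(f"paired comparison needs >= 3 pairs, got {n}")
    diff = a - b
    q1, q3 = np.percentile(diff, [25, 75])
    if a.std() == 0.0 or b.std() == 0.0:
        r, ci = float("nan"), (float("nan"), float("nan"))
    else:
        r = float(pearsonr(a, b).statistic)
        if n > 3 and abs(r) < 1.0:
            z = np.arctanh(r)
            half = 1.959963984540054 / np.sqrt(n - 3)
            ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        else:
            ci = (float("nan"), float("nan"))
    return {
        "n": n,
        "differences": diff.tolist(),
        "median_difference": float(np.median(diff)),
        "iqr_difference": float(q3 - q1),
        "pearson_r": r,
        "r_ci95": list(ci),
    }
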