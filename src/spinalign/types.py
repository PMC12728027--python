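"""Core domain types shared across the package.

The shared 3D coordinate system is the biplanar (EOS) frame:

* ``y`` — vertical, cranio-caudal, increasing cranially (mm)
* ``x`` — lateral, frontal-plane deviation (mm)
* ``z`` — antero-posterior, sagittal-plane deviation, increasing
  posteriorly (mm)

The frontal radiograph images the (x, y) plane, the lateral radiograph
the (z, y) plane.  Points and polylines are plain ``numpy`` arrays of
shape ``(3,)`` / ``(n, 3)`` in millimetres.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "View",
    "Plane",
    "RadiographFrame",
    "Annotation2D",
    "RigidTransform",
    "CorrespondenceSet",
    "CobbMeasurement",
    "SpinalignError",
    "OutOfBoundsError",
    "DegenerateGeometryError",
    "EmptyOverlapError",
    "NonMonotoneError",
    "UndefinedCorrelationError",
    "SingleCurveError",
]


class SpinalignError(ValueError):
    """Base class for domain errors raised by this package."""


class OutOfBoundsError(SpinalignError):
    """A pixel annotation lies outside the radiograph it refers to."""


class DegenerateGeometryError(SpinalignError):
    """Too few or (near-)collinear correspondences for a rigid fit."""


class EmptyOverlapError(SpinalignError):
    """Two polylines share no vertical (y) range to fuse over."""


class NonMonotoneError(SpinalignError):
    """A polyline is not acceptably monotone in y after preprocessing."""


class UndefinedCorrelationError(SpinalignError):
    """A correlation is requested on a zero-variance coordinate sequence."""


class SingleCurveError(SpinalignError):
    """A sagittal profile has no interior inflection (single curve)."""


class View(str, enum.Enum):
    """Radiographic view of a biplanar acquisition."""

    FRONTAL = "frontal"
    LATERAL = "lateral"


class Plane(str, enum.Enum):
    """Anatomical plane in which a planar quantity is evaluated.

    The frontal plane is spanned by (x, y), the sagittal plane by (z, y).
    """

    FRONTAL = "frontal"
    SAGITTAL = "sagittal"

    @property
    def coord_index(self) -> int:
        """Column index of the in-plane horizontal coordinate (x or z)."""
        return 0 if self is Plane.FRONTAL else 2


@dataclass(frozen=True)
class RadiographFrame:
    """One calibrated 2D radiographic view.

    Maps pixel indices ``(col, row)`` to millimetres in the shared 3D
    frame.  ``pixel_spacing`` is (row spacing, column spacing) in
    mm/pixel, following the DICOM ``PixelSpacing`` convention.
    ``origin_mm`` is the 3D position of the *bottom-left* image corner,
    i.e. pixel ``(col=0, row=rows-1)``: image rows run downward while
    the shared y axis points cranially, so rows are flipped during
    conversion.
    """

    view: View
    pixel_spacing: tuple[float, float]
    origin_mm: tuple[float, float, float]
    image_size_px: tuple[int, int]  # (rows, cols)
    frame_id: str = ""

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.pixel_spacing):
            raise SpinalignError(
                f"pixel_spacing must be strictly positive, got {self.pixel_spacing}"
            )
        rows, cols = self.image_size_px
        if rows < 1 or cols < 1:
            raise SpinalignError(f"image_size_px must be positive, got {self.image_size_px}")

    @property
    def origin_plane_mm(self) -> tuple[float, float]:
        """(u, y) of the bottom-left corner in this view's image plane.

        u is x for the frontal view and z for the lateral view.
        """
        ox, oy, oz = self.origin_mm
        return (ox if self.view is View.FRONTAL else oz, oy)

    def to_dict(self) -> dict:
        return {
            "view": self.view.value,
            "pixel_spacing": list(self.pixel_spacing),
            "origin_mm": list(self.origin_mm),
            "image_size_px": list(self.image_size_px),
            "frame_id": self.frame_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadiographFrame":
        return cls(
            view=View(d["view"]),
            pixel_spacing=tuple(d["pixel_spacing"]),
            origin_mm=tuple(d["origin_mm"]),
            image_size_px=tuple(int(v) for v in d["image_size_px"]),
            frame_id=d.get("frame_id", ""),
        )


@dataclass
class Annotation2D:
    """Marker picks and a drawn spine line for one radiographic view.

    ``markers`` maps marker names to ``(col, row)`` pixel coordinates
    (floats; touch picks are sub-pixel).  ``isl_polyline`` is the drawn
    internal-spine line from C7 down to L5 in pixel coordinates with at
    least two points.
    """

    frame_id: str
    markers: dict[str, tuple[float, float]]
    isl_polyline: npt.NDArray[np.float64]  # (n, 2) pixel (col, row)
    timestamp: str = ""

    def __post_init__(self) -> None:
        self.isl_polyline = np.asarray(self.isl_polyline, dtype=float)
        if self.isl_polyline.ndim != 2 or self.isl_polyline.shape[1] != 2:
            raise SpinalignError("isl_polyline must be an (n, 2) array of (col, row)")
        if len(self.isl_polyline) < 2:
            raise SpinalignError("isl_polyline needs at least 2 points")

    def validate_against(self, frame: RadiographFrame) -> None:
        """Check every annotated pixel lies inside the image bounds."""
        rows, cols = frame.image_size_px
        for name, (c, r) in self.markers.items():
            if not (0 <= c <= cols - 1 and 0 <= r <= rows - 1):
                raise OutOfBoundsError(
                    f"marker {name!r} at (col={c}, row={r}) is outside frame "
                    f"{frame.frame_id or frame.view.value} ({rows}x{cols})"
                )
        c, r = self.isl_polyline[:, 0], self.isl_polyline[:, 1]
        if (c < 0).any() or (c > cols - 1).any() or (r < 0).any() or (r > rows - 1).any():
            raise OutOfBoundsError(
                f"isl_polyline leaves frame {frame.frame_id or frame.view.value}"
            )

    def to_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "markers": {k: [float(v[0]), float(v[1])] for k, v in self.markers.items()},
            "isl_polyline": self.isl_polyline.tolist(),
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation2D":
        return cls(
            frame_id=d["frame_id"],
            markers={k: (float(v[0]), float(v[1])) for k, v in d["markers"].items()},
            isl_polyline=np.asarray(d["isl_polyline"], dtype=float),
            timestamp=d.get("timestamp", ""),
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (rotation + translation).

    Used for the postural offset between the 3D-scanner frame and the
    radiographic (EOS) frame.  The rotation must be proper orthogonal
    (R^T R = I, det R = +1) to 1e-9.
    """

    rotation: npt.NDArray[np.float64]
    translation: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise SpinalignError("rotation is not orthogonal to 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise SpinalignError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        """Apply to one point ``(3,)`` or a stack ``(n, 3)``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], float), np.asarray(d["translation"], float))


@dataclass
class CorrespondenceSet:
    """Ordered, named source/target 3D point pairs for a rigid fit.

    ``source`` are scanner-frame marker positions, ``target`` the
    triangulated radiographic marker positions.  At least three pairs
    are required and the source points must not be collinear; both are
    checked by :func:`spinalign.registration.fit_rigid`.
    """

    names: list[str]
    source: npt.NDArray[np.float64]  # (n, 3)
    target: npt.NDArray[np.float64]  # (n, 3)

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if len(self.source) != len(self.target) or len(self.source) != len(self.names):
            raise SpinalignError("names, source and target must have equal length")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class CobbMeasurement:
    """One Cobb angle between two bounding tangents of a curve segment.

    ``angle_deg`` is the unsigned clinical angle
    ``|atan(s_upper) - atan(s_lower)|`` in degrees, where the slopes are
    d(coord)/dy of the in-plane coordinate at the two bounding tangent
    points (curvature inflections or curve endpoints).  ``direction``
    is the sign of ``s_upper - s_lower`` (curve handedness); 0 for a
    flat segment.
    """

    plane: Plane
    curve_type: str  # "frontal_scoliotic" | "kyphotic" | "lordotic" | "segment"
    angle_deg: float
    lower_y: float
    upper_y: float
    slope_lower: float
    slope_upper: float
    direction: int = field(default=0)

    def __post_init__(self) -> None:
        if self.upper_y <= self.lower_y:
            raise SpinalignError("upper_y must exceed lower_y")
        expected = abs(np.degrees(np.arctan(self.slope_upper) - np.arctan(self.slope_lower)))
        if abs(expected - self.angle_deg) > 1e-6:
            raise SpinalignError("angle_deg inconsistent with stored slopes")

    def to_dict(self) -> dict:
        return {
            "plane": self.plane.value,
            "curve_type": self.curve_type,
            "angle_deg": float(self.angle_deg),
            "lower_y": float(self.lower_y),
            "upper_y": float(self.upper_y),
            "slope_lower": float(self.slope_lower),
            "slope_upper": float(self.slope_upper),
            "direction": int(self.direction),
        }
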