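"""Independent reference computations used to validate the main pipeline.

These deliberately avoid the analysis-path machinery (inflection
search, local regression): the Cobb reference below reads tangent
angles off dense central differences and takes the exact extreme tilts,
which is the direct numerical transcription of the clinical definition
("angle between the two most tilted tangents").
"""

from __future__ import annotations

import numpy as np

from .curves import SpineCurve
from .types import Plane

__all__ = ["dense_cobb_reference"]


def dense_cobb_reference(
    curve: SpineCurve, plane: Plane | str, n_dense: int = 10_000
) -> float:
    """Cobb angle by dense numerical differentiation (degrees).

    Evaluates the plane coordinate at ``n_dense`` points, forms tangent
    slopes by central differences, and returns the difference between
    the maximum and minimum tangent angles — the angle between the two
    most tilted tangents anywhere on the curve.
    """
    plane = Plane(plane)
    lo, hi = curve.y_range
    y = np.linspace(lo, hi, n_dense)
    v = curve.coord_spline(plane)(y)
    slopes = np.gradient(v, y)
    angles = np.degrees(np.arctan(slopes))
    return float(angles.max() - angles.min())
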