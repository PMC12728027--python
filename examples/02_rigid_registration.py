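"""Register scanner-frame markers onto radiographic markers.

The same skin markers are seen by the 3D scanner and (triangulated)
in the radiographs; the least-squares proper rigid transform between
the two named point sets registers the scan into the radiographic
frame.  With noisy markers the residual RMSE quantifies registration
quality, exactly as reported per patient in a clinical batch.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from spinalign import CorrespondenceSet, RigidTransform, fit_rigid, marker_rmse

rng = np.random.default_rng(0)

# four clinical markers: C7, L5 and the two posterior iliac spines (mm)
names = ["C7", "L5", "PSIS_L", "PSIS_R"]
radiographic = np.array(
    [[0.0, 450.0, 38.0], [0.0, 0.0, 35.0], [-45.0, -60.0, 20.0], [45.0, -60.0, 20.0]]
)

# ground-truth postural offset between scanner and radiograph frames
truth = RigidTransform(
    Rotation.from_euler("xyz", [2.0, -4.0, 1.0], degrees=True).as_matrix(),
    np.array([120.0, -40.0, 300.0]),
)
scanner = truth.inverse().apply(radiographic) + rng.normal(0, 2.0, (4, 3))

fitted = fit_rigid(CorrespondenceSet(names, scanner, radiographic))
rmse, per_marker, sd = marker_rmse(fitted, CorrespondenceSet(names, scanner, radiographic))

rot_err = np.degrees(
    Rotation.from_matrix(fitted.rotation @ truth.rotation.T).magnitude()
)
print(f"recovered rotation within {rot_err:.2f} deg of truth "
      f"(markers perturbed by 2 mm noise)")
print(f"marker RMSE after registration: {rmse:.2f} mm (SD {sd:.2f} mm)")
for name, r in per_marker.items():
    print(f"  {name:7s} residual {r:.2f} mm")
# RMSE ~ sigma * sqrt((3K-6)/K): with K = 4 markers and sigma = 2 mm,
# expect about 2.4 mm; individual residuals show no systematic outlier
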