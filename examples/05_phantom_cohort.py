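"""Generate a synthetic cohort, batch-process it, aggregate statistics.

Thirty phantoms are drawn from a population with median primary frontal
Cobb near 29 deg, each with 2 mm marker noise and a random postural
offset between scanner and radiograph frames.  The batch runs the full
chain per patient (triangulation, registration, smoothing, Procrustes,
correlation, Cobb) and the summary reports cohort medians and IQRs.

Equivalent CLI:
    spinalign phantom cohort/ -n 30 --seed 0
    spinalign batch cohort/ -c config.toml   # marker_names = "all"
    spinalign summarize cohort/
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from spinalign import PipelineConfig, run_batch, summarize_cohort
from spinalign.io import write_phantom_folder
from spinalign.phantom import generate_cohort

bundles = generate_cohort(30, seed=0, marker_noise_sd_mm=2.0)
truth_cobb = [b.truth.cobb_frontal_deg for b in bundles]
print(f"cohort truth: median frontal Cobb {np.median(truth_cobb):.1f} deg, "
      f"range [{min(truth_cobb):.1f}, {max(truth_cobb):.1f}]")

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    for i, bundle in enumerate(bundles):
        write_phantom_folder(bundle, root / f"patient_{i:03d}")
    results = run_batch(root, PipelineConfig(marker_names="all"))
    summary = summarize_cohort(results)

print(json.dumps(
    {k: summary[k] for k in (
        "n_processed", "marker_rmse_mm", "pcc_frontal", "pcc_sagittal",
        "cobb_frontal_primary_deg", "cobb_kyphotic_deg",
    )}, indent=2))

recovered = [r["cobb"]["frontal_primary_deg"] for r in results]
err = np.median(np.abs(np.array(recovered) - np.array(truth_cobb)))
print(f"median |recovered - truth| frontal Cobb: {err:.2f} deg")
# with 2 mm marker noise the registration RMSE sits near 3 mm (9 markers,
# 6 fitted degrees of freedom) while Cobb angles are recovered to well
# under a degree: the spine line itself is unaffected by marker noise
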