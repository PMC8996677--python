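#!/usr/bin/env python
"""Spatial ICA: recover planted subnetwork maps and compare their connectivity.

Simulates subject volumes as mixtures of three compact spatial sources
plus noise, selects the model order by MDL, unmixes with Infomax, matches
thresholded z-maps (z > 1.96) to two template masks, and scores recovery
against the planted maps.

Output: results/ica_assignment.csv, results/ica_recovery.json
"""

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from metconn import ica, synthetic

warnings.simplefilter("ignore", RuntimeWarning)
OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 31

vols, mixing_true, maps_true, atlas = synthetic.make_volume_dataset(
    (12, 12, 8), n_subjects=30, n_sources=3, noise_sd=0.1, seed=SEED
)
X = np.stack([v.data.ravel() for v in vols])

k = ica.estimate_n_components(X)
res = ica.run_ica(X, n_components=k, seed=SEED)

C = np.array([[abs(np.corrcoef(t, r)[0, 1]) for r in res.maps] for t in maps_true])
ri, ci = linear_sum_assignment(-C)
mean_corr = float(C[ri, ci].mean())

templates = ica.TemplateSet(masks={
    "dmn_like": maps_true[0] > 0.5,
    "sn_like": maps_true[1] > 0.5,
})
assign = ica.match_templates(res.z_maps, templates)
assign.to_csv(OUT / "ica_assignment.csv", index=False)

masks = [int(ica.threshold_z(res.z_maps[c]).sum()) for c in range(k)]
summary = {
    "seed": SEED,
    "mdl_selected_order": int(k),
    "true_order": 3,
    "mean_matched_abs_correlation": round(mean_corr, 4),
    "infomax_converged": bool(res.converged),
    "n_iterations": int(res.n_iter),
    "suprathreshold_voxels_per_component": masks,
}
(OUT / "ica_recovery.json").write_text(json.dumps(summary, indent=2))

print(f"MDL selected {k} components (truth: 3)")
print(f"mean matched |correlation| vs planted maps: {mean_corr:.4f}")
print(assign.to_string(index=False))
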