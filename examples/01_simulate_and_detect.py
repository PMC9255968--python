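"""Simulate a sealing zone, detect its actin cores, estimate their radii.

Builds a seeded synthetic layout (~50 cores in 8 islets, 10 x 10 um field),
renders a noisy super-resolution-like frame at 32.25 nm pixels with peak SNR
~5, runs the Find-Maxima-style detector and the Find-Edges radial-profile
radius estimator, and compares against the exported ground truth.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

import podonano as pn

layout = pn.make_layout(pn.LayoutParams(seed=1))
frame = pn.render_frame(layout, rng=1)
print(f"ground truth: {len(layout)} cores in {len(layout.islets)} islets")

cores = pn.detect_cores(frame)           # threshold = background / 2
pn.estimate_radii(frame, cores)          # 8 radial edge profiles per core
print(f"detected:     {len(cores)} cores")

dist = cdist(layout.coords_nm, cores.coords_nm)
ri, ci = linear_sum_assignment(np.where(dist <= 150.0, dist, 1e6))
matched = dist[ri, ci] <= 150.0
print(f"recall {matched.sum() / len(layout):.2f}, "
      f"median centroid error {np.median(dist[ri, ci][matched]):.1f} nm "
      f"(pixel = {frame.pixel_size_nm} nm)")
print(f"median estimated core radius: "
      f"{np.nanmedian(cores.table.radius_nm):.0f} nm "
      f"(generated around {layout.params.core_radius_nm_mean:.0f} nm; the "
      f"edge-profile estimate reads the gradient ring, a few nm inside the "
      f"nominal disc edge)")
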