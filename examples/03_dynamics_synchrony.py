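"""Time-lapse synchrony and periodicity of actin-core oscillations.

Simulates a movie (2.4 s cadence, 160 s) in which cores of the same islet
share oscillation phases (components near 0.01/0.04/0.15 Hz), extracts
per-core signals in 100 nm discs, and quantifies: the Pearson-vs-distance
synchrony curve with its half-decay distance, the prevailing Fourier
frequencies, and the growing/decreasing regions of the rate-of-change movie.
"""

import numpy as np

import podonano as pn
from podonano.core import CoreSet

layout = pn.make_layout(pn.LayoutParams(
    field_size_nm=(10000.0, 10000.0), n_islets=14, islet_radius_nm=350.0,
    cores_per_islet_mean=6.0, hard_core_nm=250.0, seed=0))
stack, truth = pn.simulate_movie(layout, pn.OscSpec(phase_model="islet_shared"),
                                 rng=100)
cores = CoreSet.from_arrays(layout.cores.x_nm, layout.cores.y_nm,
                            core_id=layout.cores.core_id)

signals = pn.extract_signals(pn.bleach_correct(stack), cores)
table = pn.pairwise_synchrony(signals)
curve = pn.synchrony_curve(table)
print(f"{len(table)} core pairs; max binned Pearson r "
      f"{np.nanmax(curve.mean_r):.2f}")
print(f"synchrony half-decay: {curve.half_decay_nm:.0f} nm "
      f"(islet diameter {2 * layout.islet_radius_nm:.0f} nm — synchrony is "
      f"local, not global)")

freqs = sorted({round(float(f), 4)
                for row in signals.values
                for f in pn.natural_frequencies(pn.spectrum(row, signals.dt_s))})
print(f"natural frequencies across cores: {freqs} Hz "
      f"(planted at 0.01/0.04/0.15 Hz; the 160 s window resolves "
      f"{1 / (signals.n_frames * signals.dt_s):.4f} Hz bins)")

rate = pn.rate_movie(stack)
regions = pn.segment_rate_clusters(rate, cores=cores)
grow = regions[regions.sign == "growing"]
print(f"rate-of-change movie: {len(grow)} growing regions over "
      f"{rate.values.shape[0]} difference frames, mean area "
      f"{grow.area_um2.mean():.2f} um^2 (coordinated polymerization patches)")
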