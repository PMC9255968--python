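# podonano

Quantitative image analysis of the osteoclast sealing zone at the nanoscale:
detection and radius estimation of podosome actin cores in super-resolution
frames, Delaunay neighbor morphometrics, time-lapse synchrony and Fourier
periodicity of actin oscillations, two-color profile and islet analysis, and
signed r–z analysis of 3-D single-molecule localizations — plus a seeded
synthetic-data generator with exported ground truth, so every stage can be
exercised and validated without any raw microscopy download.

It is written for cell biologists and image analysts working on
podosome-based adhesion structures (sealing zones on bone, podosome belts on
glass) who need a scriptable, tested version of the classical
ImageJ-plus-Python workflow used in this field.

## The quantities it computes

* **Cores.** Local maxima with prominence above a threshold (default: half
  the modal background intensity), refined to intensity-weighted centroids
  in a 200 nm disc. Core radius r is the mean over eight directions of the
  distance from the centroid to the first maximum of the Sobel-gradient
  ("Find Edges") radial profile, 1 µm long and 100 nm wide per direction.
* **Neighbor geometry.** On the Delaunay triangulation of the centroids,
  with hull–hull edges excluded: direct-neighbor distances (edge lengths,
  pooled median) and first-neighbor distances (per-vertex minima
  `min_j |x_i − x_j|` over included edges).
* **Dynamics.** Per-core signals I_i(t) in 100 nm discs; zero-lag Pearson
  r(I_i, I_j) versus pair distance, binned, with the half-decay distance of
  the curve; natural frequencies as spectral peaks above k × median
  magnitude; rate-of-change movies D_t = I_{t+1} − I_t with robust-σ
  segmentation of growing/decreasing regions; kymographs along polylines.
* **Two-color organization.** Marker profiles around cores on a
  core-radius-normalized axis; per-core actin–marker Pearson correlation in
  1 µm discs; islets segmented as adhesion-bordered enclosed regions with
  area and core count.
* **3-D localizations.** Per-core 10 µm × 200 nm boxes along and across the
  belt; signed r (positive toward the cell interior), variable-width r
  classes with per-cell median heights; radial/vertical distributions; the
  interior/exterior symmetry index (N_int − N_ext)/(N_int + N_ext).

Model details, defaults and numerical conventions are in
[docs/methods.md](docs/methods.md).

## Worked example

`examples/` holds one short script per capability. The first one simulates
a sealing zone, detects its cores and estimates radii:

```sh
$ python examples/01_simulate_and_detect.py
ground truth: 45 cores in 8 islets
detected:     46 cores
recall 1.00, median centroid error 5.7 nm (pixel = 32.25 nm)
median estimated core radius: 77 nm (generated around 100 nm; the
edge-profile estimate reads the gradient ring, a few nm inside the nominal
disc edge)
```

The detector recovers every planted core with sub-quarter-pixel centroid
accuracy; the radius estimate reads the gradient ring of each blurred core,
which sits slightly inside the nominal disc edge, plus a noise-driven early
first maximum on some profiles — hence the median a bit under the planted
100 nm. Neighbor morphometry and dynamics follow the same pattern:

```sh
$ python examples/03_dynamics_synchrony.py
2485 core pairs; max binned Pearson r 0.87
synchrony half-decay: 665 nm (islet diameter 700 nm — synchrony is local,
not global)
natural frequencies across cores: [0.0062, 0.0124, 0.0373, 0.0435, 0.1493]
Hz (planted at 0.01/0.04/0.15 Hz; the 160 s window resolves 0.0062 Hz bins)
...
```

The half-decay of the Pearson-versus-distance curve lands at the islet
diameter — actin oscillations are synchronized within an islet and
uncorrelated between islets — and the prevailing Fourier frequencies land on
the spectral bins nearest the planted components. The remaining examples
cover two-color profiles and islet segmentation (`04`) and the r–z analysis
of 3-D localizations (`05`).

A thin CLI wraps the same functions for batch use:

```sh
podonano simulate out/ --seed 1 --movie
podonano detect out/frame.tif out/cores.csv
podonano morphometry out/cores.csv out/morpho
podonano run config.yaml        # multi-stage runs with a JSON manifest
```

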