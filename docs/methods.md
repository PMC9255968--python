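# Methods

This note documents the models, parameter choices and numerical conventions
behind `podonano`, and what the synthetic-data tests do and do not establish
about real microscopy data.

## Scientific setting

Bone-resorbing osteoclasts confine their resorption compartment with the
sealing zone, a dense belt of podosome-type actin cores (~100 nm radius,
400–700 nm apart) embedded in an actin network and bordered by adhesion
complexes (vinculin, paxillin, talin, filamin A). Super-resolution imaging
shows that the cores are grouped into *islets* — clusters of a few cores
encircled by a continuous adhesion border — and that actin content
oscillates synchronously within an islet but not between islets. 3-D
single-molecule localization adds absolute protein heights above the
substrate at ~15 nm precision. The package implements the complete
quantitative workflow for these observations: core detection and radius
estimation, Delaunay neighbor morphometrics, time-lapse synchrony and
periodicity, two-color profile and islet analysis, and signed r–z analysis
of 3-D localizations — together with a generator of synthetic data with
known ground truth.

## Coordinate and unit conventions

All interfaces use nanometres for lengths, seconds for times and µm² for
areas. Images are indexed `[row, column]` = `[y, x]`; the nm origin is the
*center* of pixel (0, 0), x grows rightward and y downward. The default
pixel size is 32.25 nm (a 100× super-resolution reconstruction) and the
default frame interval 2.4 s.

## Synthetic-data generator

**Layout.** Core positions follow a Matérn-style parent–child process:
islet centers are dart-thrown uniformly with a minimum separation
(default 2.5 × islet radius, so islets are distinct but close-packed, as in
the contiguous-islet organization of a real sealing zone), member counts are
Poisson (mean 7), member positions are uniform in the islet disc, and
candidates closer than a hard-core distance (default 300 nm) to any placed
core are rejected with bounded retries. Default islet radius is 850 nm
(≈ 2.3 µm² area). A density at which the expected hard-core disc area
exceeds ~60 % of the field raises an explicit packing error. The
distributional form of islets is a modeling choice of this package, not an
inference from data.

**Spot model.** Each core is rendered as a uniform disc of its nominal
radius convolved with an isotropic Gaussian PSF (default σ = 42.5 nm,
i.e. ~100 nm FWHM lateral resolution). The convolution is evaluated exactly
per pixel through the noncentral-χ² CDF with 2 degrees of freedom. This
choice makes the generator self-consistent with the radius estimator: the
first maximum of the Sobel-gradient radial profile of a blurred disc sits at
(slightly inside) the disc edge — numerically, 6–14 nm inside for radii of
60–200 nm, well under one pixel. A pure Gaussian spot whose intensity HWHM
equals the nominal radius is available (`spot_model="gaussian"`) and is used
for closed-form intensity-mass checks; its gradient ring sits at ~0.42 × the
HWHM-matched width, so it is *not* the estimator-consistent default.

**Noise.** Poisson shot noise on the expected image plus additive Gaussian
read noise (default SD 3), on a diffuse background (default 40). With the
default peak amplitude of 50 this gives a peak SNR ≈ 5.

**Oscillations.** Per-core intensity is
`I_i(t) = base_i (1 + Σ_k a_k sin(2π f_k t + φ_{g(i),k}))` with components
defaulting to 0.01, 0.04 and 0.15 Hz at amplitude fraction 0.12 each, over
67 frames at 2.4 s (≈ 160 s). Phases are shared per islet
(`islet_shared`), independent per core, or global. Negative intensities are
clamped to zero and flagged rather than raised, so extreme-amplitude sweeps
stay runnable. Note that with *shared component frequencies*, independent
phases do **not** drive pairwise Pearson correlations to zero over a finite
window: for one component, r = cos Δφ exactly, with E|cos Δφ| = 2/π ≈ 0.64,
and ≈ 0.33 for three equal components. Unsynchronized behavior is therefore
asserted on the *binned* synchrony curve, where signed correlations cancel
(|binned mean r| ≈ 0.08 beyond 2 µm under the study conditions), not on the
mean of |r| over pairs.

**Localizations.** Lateral positions follow the protein's model
(core-centered Gaussian with σ = core radius; ring at a given offset from
the core edge; annulus around islet centers), and are blurred by the
localization precision (default 15 nm). Heights are
`z ~ N(axial_mean + slope · d_interior, precision)` where `d_interior` is
the signed distance from the belt line (through the core centroid) along the
interior normal, in µm.

**What the generator does not emulate:** speckle statistics and
reconstruction artifacts of the upstream imaging, spatially correlated
noise, core shape anisotropy, core motion, axial PSF structure, and
background gradients. Passing tests therefore establish correctness of the
*analysis* given the stated image-formation model, not performance on any
particular instrument's data.

## Detection

Background is estimated as the modal intensity (robust to bright sparse
structure; median selectable). The detection threshold defaults to half the
background, used as a *prominence* tolerance: maxima are h-maxima of the
image, i.e. peaks at least that far above their highest saddle toward higher
terrain, in an 8-connected neighborhood. Detection runs on a lightly
smoothed copy of the frame (Gaussian σ = 0.5 px, configurable, 0 disables):
real reconstructed images are band-limited by the PSF, whereas the
generator's pixel-independent noise would otherwise contribute spurious
single-pixel maxima that no band-limited image would show. Candidates
closer than the 200 nm weighting radius are merged (brighter wins — two
maxima inside one weighting disc would yield near-identical centroids), and
each kept maximum is refined to the background-subtracted intensity-weighted
centroid of the pixels within 200 nm. Under the default study conditions
(~200 cores, peak SNR 5) this yields recall and precision ≥ 0.95 with a
median centroid error of ~8 nm (a quarter pixel).

The "Find Edges" transform is the un-normalized 3×3 Sobel magnitude
(step of height h → interior response 4h) with replicate borders. Radial
profiles are sampled at one-pixel steps along 8 rays, averaged across a
100 nm width by bilinear interpolation; rays leaving the image are flagged
clipped. The per-direction radius is the distance to the first local
maximum of the edge profile, refined by a three-point parabolic fit (the
32 nm pixel is comparable to the effect sizes measured, so sub-pixel
refinement matters); the core radius is the mean over unflagged directions,
and it is reported missing — never zero — when all eight are flagged.
Clipped directions are excluded from the average.

## Morphometry

The Delaunay triangulation and convex hull come from Qhull
(`scipy.spatial`); cocircular degeneracies are broken by the triangulator's
joggle/perturbation, deterministic per input. Edges whose two endpoints both
lie on the hull are excluded; hull-to-interior edges are retained. Direct
neighbor statistics report both the per-vertex mean of included incident
edges and the pooled edge-length distribution — published summaries use
either convention — with the pooled median as the headline number (the
choice is visible in the output schema). First-neighbor distances are
per-vertex minima; for interior vertices these provably equal the global
nearest-neighbor distance, which is tested against an O(n²) oracle, and the
whole edge set is tested against an O(n⁴) empty-circumcircle enumeration.

## Dynamics

Bleach correction matches each frame's histogram monotonically to frame 0
(constant frames pass through unchanged). Per-core signals are disc means
(100 nm radius; membership by pixel centers, computed once). Pearson
correlation is computed at zero lag only, after linear detrending by default
(a raw mode exists); zero-variance signals yield undefined r, excluded and
counted. The synchrony curve bins pairs by distance (100 nm default) and
reports the half-decay distance — the first crossing of half the maximum
binned mean, linearly interpolated — as missing when the curve never
crosses. Spectra are magnitudes of the real-input DFT of mean-subtracted,
linearly detrended signals; natural frequencies are non-DC local maxima
exceeding k × the median non-DC magnitude. The proportionality constant is
not fixed by the procedure this reimplements; the default k = 5 is exposed
in the API and recorded in outputs, and the null false-positive check uses
k = 20. The rate-of-change movie is the first difference along time,
Gaussian-smoothed with σ = radius/2 (the ImageJ "radius ≈ 2σ" convention,
default radius 64.5 nm = 2 px) and averaged over a centered 3-frame window
with truncated windows at the ends; disabling both reduces it to the exact
telescoping identity. Cluster segmentation thresholds each difference frame
at ±z × (1.4826 · MAD) — a robust σ, since rate maps are heavy-tailed —
labels 8-connected components, and drops those below a minimum area.
Integer-pixel phase-correlation registration is provided as optional
preprocessing; full feature-based registration is out of scope.

## Two-color profiles and islets

The local belt orientation is the first principal axis of the neighbor
coordinates within 1.5 µm (user-supplied angles can override it; the
automated estimate exists because batch processing needs one). Axis ratios
below 1.2 are flagged low-confidence. Line profiles are 1.5 µm long and
100 nm wide, longitudinal and transverse per core, sampled on the actin,
edge and marker channels simultaneously; border-clipped cores are excluded
and counted. Pooling rescales each profile's axis by the median core radius
(from the first edge maxima on both sides of each profile), interpolates
linearly onto a ±6-unit grid in steps of 1/8 unit, takes per-position
medians across cores and orientations, and min-max normalizes each channel
to [0, 1] — making the pooled profiles invariant to per-channel affine
intensity transforms. Per-core actin–marker correlation uses disc means in
1 µm circles, each channel normalized by its maximum over cores, with
Pearson r across cores (undefined below 3 cores or for a zero-variance
channel).

Islet segmentation reconstructs the observable "cores encircled by adhesion
borders": the adhesion channel is thresholded (Otsu by default, for a
parameter-light method; a fixed threshold can be passed), the complement of
the border mask is labeled (4-connectivity, so islets do not leak through
diagonal border gaps), components touching the image border (the unbounded
outside) or smaller than a minimum area are dropped, and core centroids are
counted per islet. The delineation is an automated reconstruction, labeled
as such; no manual protocol is emulated.

## r–z localization analysis

Each core gets two 10 µm × 200 nm boxes, along the belt axis and along the
interior normal; localizations inside a box keep their z and get r = the
signed projection onto the box axis. Transverse r is positive toward the
cell interior; the along-belt sign follows the fixed reference orientation
of the axis (interior/exterior is undefined along the belt) and pooled
summaries treat it as unsigned. A localization may fall in several cores'
boxes and is assigned to each, with the multiplicity visible in the output.
Bins are half-open [low, high), 100 nm wide to ±1 µm and 500 nm beyond to
±5 µm, with 0 in the first interior-side bin; bin medians are computed per
cell by pooling that cell's cores, and empty bins are absent rather than
zero. Pooled median heights aggregate per-cell medians (median of medians)
so unequally sampled cells contribute equally. The symmetry index is
(N_interior − N_exterior)/(N_interior + N_exterior) on transverse points
with r ≠ 0, per cell. Boxes are not clipped at cell borders.

## Pipeline and provenance

`run_pipeline` executes simulate → detect → morphometry → dynamics from a
single validated config (unknown keys rejected before any stage runs) and
writes a JSON manifest with all parameters, the seed, the package version,
input checksums and every output file; a failed stage is recorded with its
error and completed outputs are left intact. All generator outputs are pure
functions of their parameters and seed.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical claims are stable:
oracle comparisons over 100 seeds at n ≤ 50 points; detection on a single
~200-core field; synchrony on 10 movie seeds of ~70 cores × 67 frames
(310² px); frequency recovery on 167-sample signals; localization analyses
at n = 5000–20000 per protein. Real studies pool thousands of cores over
many cells; the statistical machinery is identical, only n changes.

## Known limitations

* The detector is tuned for dense, roughly isotropic spots on a smooth
  background; elongated or overlapping structures will merge or split.
* Radius estimates carry a small negative bias (the gradient ring of a
  blurred disc sits inside the disc edge, and noise can trigger early first
  maxima on raw edge profiles); noise-free bias is < 1 px but noisy-frame
  medians run ~15–20 % low at SNR 5.
* Histogram-matching bleach correction assumes the intensity *distribution*
  is stationary; it will distort stacks with genuine global remodeling.
* Otsu-based islet segmentation requires a bimodal adhesion histogram;
  sparse or dim borders need a manual threshold.
* Pearson synchrony is zero-lag only; traveling waves would appear as
  reduced synchrony, not as lagged correlation.
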