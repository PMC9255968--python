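"""Time-lapse analysis of sealing-zone actin dynamics.

Per-core intensity signals are read out in small discs around each core,
pairwise synchrony is quantified by the zero-lag Pearson correlation as a
function of inter-core distance, periodicity by the discrete Fourier spectrum
of each (detrended) signal, and net polymerization/depolymerization by a
smoothed frame-difference ("rate of change") movie with connected-component
segmentation of coordinated regions.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps
from scipy.spatial.distance import pdist
from skimage import exposure, measure

from .core import CoreSet, Image2D, ImageStack

__all__ = [
    "SignalMatrix", "Spectrum", "RateMap", "SynchronyCurve", "Kymograph",
    "bleach_correct", "register_translation", "extract_signals",
    "pairwise_synchrony", "synchrony_curve", "spectrum",
    "natural_frequencies", "rate_movie", "segment_rate_clusters", "kymograph",
]


# ---------------------------------------------------------------------------
# containers

@dataclasses.dataclass
class SignalMatrix:
    """Per-core intensity time series (cores x T)."""

    core_ids: np.ndarray
    coords_nm: np.ndarray
    values: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("signal matrix has missing values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values,
                          columns=[f"t{j}" for j in range(self.n_frames)])
        df.insert(0, "core_id", self.core_ids)
        df.insert(1, "x_nm", self.coords_nm[:, 0])
        df.insert(2, "y_nm", self.coords_nm[:, 1])
        df.to_csv(path, index=False)


@dataclasses.dataclass
class Spectrum:
    """Magnitude spectrum of one signal, DC to Nyquist."""

    frequencies_Hz: np.ndarray
    magnitudes: np.ndarray
    detrend: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("non-finite spectrum")


@dataclasses.dataclass
class RateMap:
    """Signed frame-difference stack: positive = net polymerization."""

    values: np.ndarray           # (T-1, H, W)
    dt_s: float
    pixel_size_nm: float
    gaussian_radius_nm: float | None
    temporal_window: int


@dataclasses.dataclass
class SynchronyCurve:
    """Binned mean Pearson r vs distance, with its half-decay distance."""

    bin_centers_nm: np.ndarray
    mean_r: np.ndarray           # NaN for empty bins
    counts: np.ndarray
    half_decay_nm: float         # NaN when the curve never falls to half max


@dataclasses.dataclass
class Kymograph:
    """Arc-length x time intensity image along a polyline."""

    values: np.ndarray           # (n_positions, T)
    pixel_size_nm: float
    dt_s: float
    polyline_nm: np.ndarray


# ---------------------------------------------------------------------------
# preprocessing

def bleach_correct(stack: ImageStack,
                   method: Literal["histogram_matching"] = "histogram_matching",
                   ) -> ImageStack:
    """Normalize intensities across a stack by histogram matching to frame 0.

    Each frame's histogram is monotonically remapped to match the first
    frame's; frame 0 (and any constant frame) is returned unchanged.
    """
    if method != "histogram_matching":
        raise ValueError(f"unknown bleach-correction method {method!r}")
    ref = stack.frames[0]
    out = np.empty_like(stack.frames)
    out[0] = ref
    for t in range(1, stack.n_frames):
        frame = stack.frames[t]
        if np.ptp(frame) == 0:
            out[t] = frame
        else:
            out[t] = exposure.match_histograms(frame, ref)
    return ImageStack(out, stack.dt_s, stack.pixel_size_nm, stack.channel_label)


def register_translation(stack: ImageStack) -> ImageStack:
    """Integer-pixel translational registration to frame 0 by phase correlation.

    Lightweight drift-removal preprocessing for live stacks; rotation and
    scaling are not modeled.
    """
    ref_f = np.fft.rfft2(stack.frames[0])
    out = stack.frames.copy()
    for t in range(1, stack.n_frames):
        cross = ref_f * np.conj(np.fft.rfft2(stack.frames[t]))
        denom = np.abs(cross)
        corr = np.fft.irfft2(np.where(denom > 0, cross / denom, 0),
                             s=stack.frames[0].shape)
        shift = np.unravel_index(np.argmax(corr), corr.shape)
        shift = [s - n if s > n // 2 else s
                 for s, n in zip(shift, corr.shape)]
        out[t] = np.roll(stack.frames[t], shift, axis=(0, 1))
    return ImageStack(out, stack.dt_s, stack.pixel_size_nm, stack.channel_label)


# ---------------------------------------------------------------------------
# signals and synchrony

def extract_signals(stack: ImageStack, cores: CoreSet,
                    radius_nm: float = 100.0) -> SignalMatrix:
    """Mean intensity per frame in a disc of ``radius_nm`` around each core.

    Disc membership (pixels whose centers fall within the radius of the core
    centroid) is computed once and reused across frames.
    """
    ps = stack.pixel_size_nm
    tframes, h, w = stack.frames.shape
    flat = stack.frames.reshape(tframes, -1)
    coords = cores.coords_nm
    values = np.empty((len(cores), tframes))
    for i, (x, y) in enumerate(coords):
        if not (-0.5 <= x / ps <= w - 0.5 and -0.5 <= y / ps <= h - 0.5):
            raise ValueError(f"core {cores.ids[i]} outside frame bounds")
        cx, cy = x / ps, y / ps
        r0 = max(int(np.floor(cy - radius_nm / ps)), 0)
        r1 = min(int(np.ceil(cy + radius_nm / ps)) + 1, h)
        c0 = max(int(np.floor(cx - radius_nm / ps)), 0)
        c1 = min(int(np.ceil(cx + radius_nm / ps)) + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= (radius_nm / ps) ** 2
        idx = (rr[disc] * w + cc[disc]).ravel()
        if idx.size == 0:
            raise ValueError(
                f"disc of radius {radius_nm} nm contains no pixel centers "
                f"(pixel size {ps} nm)")
        values[i] = flat[:, idx].mean(axis=1)
    return SignalMatrix(cores.ids, coords, values, stack.dt_s)


def pairwise_synchrony(signals: SignalMatrix,
                       detrend: bool = True) -> pd.DataFrame:
    """Distance and zero-lag Pearson r for every unordered core pair.

    Signals are linearly detrended by default (removes bleach residue) before
    correlating.  Pairs involving a zero-variance signal get ``r = NaN``; the
    number of such excluded signals is stored in ``DataFrame.attrs``.
    """
    n, tlen = signals.values.shape
    if n < 2:
        raise ValueError("need at least 2 cores")
    if tlen < 3:
        raise ValueError("need at least 3 time points")
    x = sps.detrend(signals.values, axis=1) if detrend else signals.values
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (x - x.mean(axis=1, keepdims=True))
        denom = np.outer(sd, sd) * tlen
        corr = (xc @ xc.T) / np.where(denom > 0, denom, np.nan)
    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    r[degenerate[iu] | degenerate[ju]] = np.nan
    dist = pdist(signals.coords_nm)
    table = pd.DataFrame({
        "core_i": signals.core_ids[iu], "core_j": signals.core_ids[ju],
        "distance_nm": dist, "pearson_r": np.clip(r, -1.0, 1.0),
    })
    table.attrs["n_zero_variance"] = int(degenerate.sum())
    table.attrs["detrend"] = detrend
    return table


def synchrony_curve(table: pd.DataFrame,
                    bin_width_nm: float = 100.0) -> SynchronyCurve:
    """Bin mean Pearson r by distance and locate the half-decay distance.

    The half-decay distance is where the binned mean first falls to half of
    the maximum binned mean, linearly interpolated between bin centers; NaN
    when the curve never crosses (e.g. constant r).
    """
    if len(table) == 0:
        raise ValueError("empty synchrony table")
    ok = table.dropna(subset=["pearson_r"])
    if len(ok) == 0:
        raise ValueError("all Pearson coefficients undefined")
    d = ok["distance_nm"].to_numpy()
    r = ok["pearson_r"].to_numpy()
    n_bins = int(np.floor(d.max() / bin_width_nm)) + 1
    idx = np.minimum((d // bin_width_nm).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width_nm

    target = np.nanmax(mean_r) / 2.0
    half = float("nan")
    prev: tuple[float, float] | None = None
    for c, v in zip(centers, mean_r):
        if np.isnan(v):
            continue
        if v <= target:
            if prev is None:
                half = float(c)
            else:
                pc, pv = prev
                half = float(pc + (pv - target) / (pv - v) * (c - pc))
            break
        prev = (float(c), float(v))
    return SynchronyCurve(centers, mean_r, counts, half)


# ---------------------------------------------------------------------------
# spectra

def spectrum(values: np.ndarray, dt_s: float,
             detrend: Literal["linear", "none"] = "linear") -> Spectrum:
    """Magnitude of the real-input DFT of a (detrended) signal.

    The frequency axis runs from 0 to the Nyquist frequency ``1/(2 dt)`` with
    spacing ``1/(T dt)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectrum expects a 1-D signal")
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal has non-finite samples")
    if detrend == "linear":
        x = sps.detrend(x - x.mean())
    elif detrend != "none":
        raise ValueError(f"unknown detrend mode {detrend!r}")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=dt_s)
    return Spectrum(freqs, mags, detrend)


def natural_frequencies(spec: Spectrum, k_median: float = 5.0) -> np.ndarray:
    """Prominent oscillation frequencies of a spectrum.

    Local maxima of the magnitude spectrum (DC excluded) whose magnitude
    exceeds ``k_median`` times the median non-DC magnitude, in ascending
    frequency order.  An empty result is valid (no periodicity detected);
    detections are invariant to overall signal scaling since the threshold is
    relative.
    """
    if k_median <= 0:
        raise ValueError("k_median must be positive")
    m = spec.magnitudes
    if len(m) < 4:
        return np.array([])
    med = np.median(m[1:])
    thresh = k_median * med
    out = []
    for i in range(1, len(m) - 1):
        if m[i] > m[i - 1] and m[i] >= m[i + 1] and m[i] > thresh:
            out.append(spec.frequencies_Hz[i])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# rate-of-change movies

def rate_movie(stack: ImageStack, gaussian_radius_nm: float | None = 64.5,
               temporal_window: int = 3) -> RateMap:
    """Frame-difference movie: ``D_t = I_{t+1} - I_t``, smoothed.

    Spatial smoothing uses a Gaussian with sigma = radius / 2 (the ImageJ
    "radius ~ 2 sigma" convention); temporal smoothing is a centered moving
    mean over ``temporal_window`` difference frames with shorter windows at
    the ends.  Pass ``gaussian_radius_nm=None`` and ``temporal_window=1`` for
    the raw telescoping differences.
    """
    diff = np.diff(stack.frames, axis=0)
    if gaussian_radius_nm:
        sigma_px = (gaussian_radius_nm / 2.0) / stack.pixel_size_nm
        diff = ndimage.gaussian_filter(diff, (0, sigma_px, sigma_px))
    if temporal_window > 1:
        nt = diff.shape[0]
        half_lo = (temporal_window - 1) // 2
        half_hi = temporal_window // 2
        prefix = np.concatenate([np.zeros((1,) + diff.shape[1:]),
                                 np.cumsum(diff, axis=0)])
        t = np.arange(nt)
        lo = np.maximum(t - half_lo, 0)
        hi = np.minimum(t + half_hi + 1, nt)
        diff = (prefix[hi] - prefix[lo]) / (hi - lo)[:, None, None]
    return RateMap(diff, stack.dt_s, stack.pixel_size_nm, gaussian_radius_nm,
                   temporal_window)


def segment_rate_clusters(rate: RateMap, z_thresh: float = 2.0,
                          min_area_um2: float = 0.05,
                          cores: CoreSet | None = None) -> pd.DataFrame:
    """Label coordinated growing/decreasing regions per frame.

    Pixels above ``+z_thresh * sigma`` (robust per-frame sigma = 1.4826 MAD)
    are "growing", below ``-z_thresh * sigma`` "decreasing"; 8-connected
    components smaller than ``min_area_um2`` are discarded.  Returns one row
    per region with frame, sign, area, centroid and (when ``cores`` is given)
    the member core ids.
    """
    ps = rate.pixel_size_nm
    px_area_um2 = (ps / 1000.0) ** 2
    rows = []
    core_px = None
    if cores is not None:
        core_px = np.rint(cores.coords_nm / ps).astype(int)  # (N, 2) x, y
    for t, frame in enumerate(rate.values):
        mad = np.median(np.abs(frame - np.median(frame)))
        sigma = 1.4826 * mad
        if sigma == 0:
            continue
        for sign, mask in (("growing", frame > z_thresh * sigma),
                           ("decreasing", frame < -z_thresh * sigma)):
            labels = measure.label(mask, connectivity=2)
            for region in measure.regionprops(labels):
                area = region.area * px_area_um2
                if area < min_area_um2:
                    continue
                cy, cx = region.centroid
                members: list = []
                if core_px is not None:
                    inside = labels[
                        np.clip(core_px[:, 1], 0, labels.shape[0] - 1),
                        np.clip(core_px[:, 0], 0, labels.shape[1] - 1),
                    ] == region.label
                    members = list(np.asarray(cores.ids)[inside])
                rows.append((t, sign, area, cx * ps, cy * ps, members))
    return pd.DataFrame(rows, columns=["frame", "sign", "area_um2",
                                       "centroid_x_nm", "centroid_y_nm",
                                       "core_ids"])


# ---------------------------------------------------------------------------
# kymographs

def kymograph(stack: ImageStack, polyline_nm: np.ndarray,
              width_nm: float = 100.0) -> Kymograph:
    """Intensity along a polyline versus time.

    The polyline is resampled at one-pixel arc-length steps; at each step the
    intensity is averaged across ``width_nm`` perpendicular to the local
    segment direction.  Rows are positions, columns are time.
    """
    poly = np.asarray(polyline_nm, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an (M >= 2, 2) array of nm points")
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        raise ValueError("zero-length polyline")
    ps = stack.pixel_size_nm
    n_steps = int(np.ceil(total / ps))
    s = np.arange(n_steps) * ps
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                      len(seg) - 1)
    frac = (s - cum[seg_idx]) / np.where(seg_len[seg_idx] > 0,
                                         seg_len[seg_idx], 1.0)
    pts = poly[seg_idx] + frac[:, None] * seg[seg_idx]
    tang = seg[seg_idx] / seg_len[seg_idx][:, None]
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])

    n_off = max(int(round(width_nm / ps)), 1)
    offsets = (np.arange(n_off) - (n_off - 1) / 2) * ps
    sample = pts[None, :, :] + offsets[:, None, None] * norm[None, :, :]
    ys = sample[..., 1].ravel() / ps
    xs = sample[..., 0].ravel() / ps

    h, w = stack.frames.shape[1:]
    if (xs < 0).any() or (xs > w - 1).any() or (ys < 0).any() or (ys > h - 1).any():
        raise ValueError("polyline footprint leaves the frame")
    values = np.empty((n_steps, stack.n_frames))
    for t in range(stack.n_frames):
        samp = ndimage.map_coordinates(stack.frames[t], [ys, xs], order=1)
        values[:, t] = samp.reshape(n_off, n_steps).mean(axis=0)
    return Kymograph(values, ps, stack.dt_s, poly)
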