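"""Two-color fixed-sample analysis relative to actin cores.

Oriented line profiles of a marker channel around each core (1.5 um long,
100 nm wide, longitudinal and transverse to the local belt orientation),
core-width normalization and pooled median profiles, per-core actin-marker
intensity correlation in 1 um discs, and islet segmentation from an
adhesion-marker image (islets = connected regions enclosed by the adhesion
border network).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .core import CoreSet, Image2D
from .detection import _first_local_max

__all__ = ["BeltAngle", "LineProfileSet", "NormalizedProfiles",
           "local_belt_angle", "extract_line_profiles", "normalize_and_pool",
           "core_marker_correlation", "segment_islets"]

CHANNELS = ("actin", "edge", "marker")


@dataclasses.dataclass
class BeltAngle:
    """Local belt orientation from neighbor PCA, in (-90, 90] degrees."""

    angle_deg: float
    axis_ratio: float
    confident: bool   # False when the neighborhood is near-isotropic


def local_belt_angle(cores: CoreSet, core_index: int,
                     neighborhood_radius_nm: float = 1500.0,
                     min_axis_ratio: float = 1.2) -> BeltAngle:
    """Estimate the local sealing-zone orientation around one core.

    The angle of the first principal axis of the neighbor coordinates
    (cores within ``neighborhood_radius_nm``, the center included).  When the
    neighborhood is nearly isotropic (axis ratio below ``min_axis_ratio``)
    the estimate is flagged low-confidence.
    """
    coords = cores.coords_nm
    center = coords[core_index]
    d = np.hypot(*(coords - center).T)
    nb = coords[d <= neighborhood_radius_nm]
    if len(nb) < 3:
        raise ValueError("need >= 3 cores within the neighborhood radius")
    cov = np.cov((nb - nb.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    angle = np.rad2deg(np.arctan2(v[1], v[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    ratio = float(np.sqrt(evals[-1] / evals[0])) if evals[0] > 0 else np.inf
    return BeltAngle(float(angle), ratio, ratio >= min_axis_ratio)


@dataclasses.dataclass
class LineProfileSet:
    """Per-core oriented line profiles of three co-registered channels.

    ``channels[name]`` has shape ``(n_cores, 2, P)`` — orientation 0 is
    longitudinal (along the belt), 1 transverse; ``positions_nm`` is the
    signed position axis with 0 at the core center.
    """

    positions_nm: np.ndarray
    core_ids: np.ndarray
    channels: dict[str, np.ndarray]
    excluded_ids: list

    @property
    def n_cores(self) -> int:
        return len(self.core_ids)

    def to_csv(self, path) -> None:
        rows = []
        for name, arr in self.channels.items():
            for i, cid in enumerate(self.core_ids):
                for o, orient in enumerate(("longitudinal", "transverse")):
                    for p, v in zip(self.positions_nm, arr[i, o]):
                        rows.append((cid, name, orient, p, v))
        pd.DataFrame(rows, columns=["core_id", "channel", "orientation",
                                    "position_nm", "intensity"]
                     ).to_csv(path, index=False)


def _sample_line(img: Image2D, center_nm, angle_deg: float,
                 positions_nm: np.ndarray, width_nm: float):
    """Width-averaged bilinear samples along an oriented line.

    Returns ``(values, clipped)``.
    """
    ps = img.pixel_size_nm
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), np.sin(th)])
    v = np.array([-np.sin(th), np.cos(th)])
    n_off = max(int(round(width_nm / ps)), 1)
    offsets = (np.arange(n_off) - (n_off - 1) / 2) * ps
    pts = (np.asarray(center_nm)[None, None, :]
           + positions_nm[None, :, None] * u[None, None, :]
           + offsets[:, None, None] * v[None, None, :])
    xs = pts[..., 0].ravel() / ps
    ys = pts[..., 1].ravel() / ps
    h, w = img.pixels.shape
    clipped = bool(((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)).any())
    samp = ndimage.map_coordinates(img.pixels, [ys, xs], order=1,
                                   mode="nearest")
    return samp.reshape(n_off, len(positions_nm)).mean(axis=0), clipped


def extract_line_profiles(actin: Image2D, edge: Image2D, marker: Image2D,
                          cores: CoreSet, angles_deg: np.ndarray,
                          length_nm: float = 1500.0,
                          width_nm: float = 100.0) -> LineProfileSet:
    """Centered longitudinal/transverse profiles of three channels per core.

    ``angles_deg`` gives each core's longitudinal (belt) direction; the
    transverse profile is at +90 degrees.  Cores whose profile footprint is
    clipped by the image border are excluded and their ids reported.
    """
    imgs = {"actin": actin, "edge": edge, "marker": marker}
    ps = actin.pixel_size_nm
    for name, im in imgs.items():
        if im.pixel_size_nm != ps or im.pixels.shape != actin.pixels.shape:
            raise ValueError(f"channel {name!r} is not co-registered")
    angles_deg = np.broadcast_to(np.asarray(angles_deg, dtype=float),
                                 (len(cores),))
    half_steps = int(np.floor((length_nm / 2) / ps))
    positions = np.arange(-half_steps, half_steps + 1) * ps

    kept_ids, excluded = [], []
    data = {name: [] for name in CHANNELS}
    for i in range(len(cores)):
        center = cores.coords_nm[i]
        profiles = {name: np.empty((2, len(positions))) for name in CHANNELS}
        clipped = False
        for o, ang in enumerate((angles_deg[i], angles_deg[i] + 90.0)):
            for name, im in imgs.items():
                vals, clip = _sample_line(im, center, ang, positions, width_nm)
                profiles[name][o] = vals
                clipped |= clip
        if clipped:
            excluded.append(cores.ids[i])
            continue
        kept_ids.append(cores.ids[i])
        for name in CHANNELS:
            data[name].append(profiles[name])
    channels = {name: (np.asarray(data[name]) if data[name]
                       else np.empty((0, 2, len(positions))))
                for name in CHANNELS}
    return LineProfileSet(positions, np.asarray(kept_ids), channels, excluded)


@dataclasses.dataclass
class NormalizedProfiles:
    """Pooled median profiles on a core-radius-normalized axis.

    Positions are in units of the median core radius; each channel's median
    profile is min-max normalized to [0, 1].
    """

    positions_units: np.ndarray
    profiles: dict[str, np.ndarray]
    median_radius_nm: float
    n_cores: int

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"position_units": self.positions_units,
                           **self.profiles})
        df.to_csv(path, index=False)


def _edge_radius(positions_nm: np.ndarray, edge_profile: np.ndarray) -> float:
    """Core radius from a centered edge profile: mean of the first edge
    maxima on the two sides; NaN when neither side has one."""
    zero = int(np.argmin(np.abs(positions_nm)))
    sides = []
    pos = _first_local_max(edge_profile[zero:])
    if not np.isnan(pos):
        sides.append(pos * (positions_nm[1] - positions_nm[0]))
    neg = _first_local_max(edge_profile[zero::-1])
    if not np.isnan(neg):
        sides.append(neg * (positions_nm[1] - positions_nm[0]))
    return float(np.mean(sides)) if sides else float("nan")


def normalize_and_pool(profiles: LineProfileSet,
                       grid_step_units: float = 0.125,
                       grid_span_units: float = 6.0) -> NormalizedProfiles:
    """Pool line profiles on a median-core-radius axis.

    The median core radius is computed from the first maxima of the edge
    profiles over all cores and orientations; every profile's position axis
    is rescaled so one unit equals that radius, interpolated onto a common
    grid (+-``grid_span_units`` in steps of ``grid_step_units``), the
    per-position median is taken across cores and orientations, and each
    channel is min-max normalized to [0, 1].
    """
    if profiles.n_cores == 0:
        raise ValueError("no profiles to pool")
    radii = []
    for i in range(profiles.n_cores):
        for o in range(2):
            r = _edge_radius(profiles.positions_nm,
                             profiles.channels["edge"][i, o])
            if np.isfinite(r):
                radii.append(r)
    if not radii:
        raise ValueError("no edge maxima found in any profile")
    median_radius = float(np.median(radii))

    grid = np.arange(-grid_span_units, grid_span_units + grid_step_units / 2,
                     grid_step_units)
    scaled_pos = profiles.positions_nm / median_radius
    pooled: dict[str, np.ndarray] = {}
    for name, arr in profiles.channels.items():
        stackd = []
        for i in range(profiles.n_cores):
            for o in range(2):
                vals = np.interp(grid, scaled_pos, arr[i, o],
                                 left=np.nan, right=np.nan)
                stackd.append(vals)
        with np.errstate(all="ignore"):
            med = np.nanmedian(np.asarray(stackd), axis=0)
        lo, hi = np.nanmin(med), np.nanmax(med)
        pooled[name] = (med - lo) / (hi - lo) if hi > lo else np.zeros_like(med)
    return NormalizedProfiles(grid, pooled, median_radius, profiles.n_cores)


@dataclasses.dataclass
class CorrelationResult:
    """Per-core mean intensities of two channels and their Pearson r."""

    per_core: pd.DataFrame
    pearson_r: float
    reason: str = ""


def core_marker_correlation(actin: Image2D, marker: Image2D, cores: CoreSet,
                            radius_nm: float = 1000.0) -> CorrelationResult:
    """Correlate actin and marker content in 1 um discs around each core.

    Per core, the mean intensity of both channels inside the disc; each
    channel is normalized by its maximum over cores; the Pearson correlation
    across cores is reported (NaN with a reason for < 3 cores or a
    zero-variance channel).
    """
    if (marker.pixel_size_nm != actin.pixel_size_nm
            or marker.pixels.shape != actin.pixels.shape):
        raise ValueError("marker channel is not co-registered with actin")
    ps = actin.pixel_size_nm
    h, w = actin.pixels.shape
    means = np.empty((len(cores), 2))
    for i, (x, y) in enumerate(cores.coords_nm):
        cx, cy = x / ps, y / ps
        r_px = radius_nm / ps
        r0 = max(int(np.floor(cy - r_px)), 0)
        r1 = min(int(np.ceil(cy + r_px)) + 1, h)
        c0 = max(int(np.floor(cx - r_px)), 0)
        c1 = min(int(np.ceil(cx + r_px)) + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= r_px ** 2
        means[i, 0] = actin.pixels[r0:r1, c0:c1][disc].mean()
        means[i, 1] = marker.pixels[r0:r1, c0:c1][disc].mean()
    norm = means / np.where(means.max(axis=0) > 0, means.max(axis=0), 1.0)
    per_core = pd.DataFrame({
        "core_id": cores.ids, "actin_mean": means[:, 0],
        "marker_mean": means[:, 1], "actin_norm": norm[:, 0],
        "marker_norm": norm[:, 1],
    })
    if len(cores) < 3:
        return CorrelationResult(per_core, float("nan"), "fewer than 3 cores")
    if norm[:, 0].std() == 0 or norm[:, 1].std() == 0:
        return CorrelationResult(per_core, float("nan"),
                                 "zero-variance channel")
    r = float(np.corrcoef(norm[:, 0], norm[:, 1])[0, 1])
    return CorrelationResult(per_core, r)


def segment_islets(adhesion: Image2D, cores: CoreSet,
                   min_area_um2: float = 0.2,
                   threshold: Literal["otsu"] | float = "otsu",
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment islets enclosed by the adhesion-marker border network.

    The adhesion image is thresholded (Otsu by default) to a border mask;
    connected components of the mask complement are islet candidates, the
    unbounded outside (components touching the image border) and components
    below ``min_area_um2`` are dropped, and core centroids are counted per
    islet.

    Returns ``(stats, labels)`` where ``stats`` has one row per islet
    (``islet_id, area_um2, n_cores, core_ids``) and ``labels`` is the islet
    label image (0 = no islet).
    """
    img = adhesion.pixels
    ps = adhesion.pixel_size_nm
    empty = (pd.DataFrame(columns=["islet_id", "area_um2", "n_cores",
                                   "core_ids"]),
             np.zeros_like(img, dtype=int))
    if np.ptp(img) == 0:
        return empty
    thr = filters.threshold_otsu(img) if threshold == "otsu" else float(threshold)
    border = img > thr
    if not border.any():
        return empty
    labels = measure.label(~border, connectivity=1)
    edge_labels = np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
    px_area_um2 = (ps / 1000.0) ** 2
    core_px = np.rint(cores.coords_nm / ps).astype(int) if len(cores) else \
        np.empty((0, 2), int)
    core_labels = labels[np.clip(core_px[:, 1], 0, labels.shape[0] - 1),
                         np.clip(core_px[:, 0], 0, labels.shape[1] - 1)] \
        if len(core_px) else np.array([], int)

    rows = []
    out_labels = np.zeros_like(labels)
    islet_id = 0
    for region in measure.regionprops(labels):
        if region.label in edge_labels:
            continue
        area = region.area * px_area_um2
        if area < min_area_um2:
            continue
        member = np.asarray(cores.ids)[core_labels == region.label] \
            if len(core_px) else np.array([])
        rows.append((islet_id, area, len(member), list(member)))
        out_labels[labels == region.label] = islet_id + 1
        islet_id += 1
    stats = pd.DataFrame(rows, columns=["islet_id", "area_um2", "n_cores",
                                        "core_ids"])
    return stats, out_labels
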