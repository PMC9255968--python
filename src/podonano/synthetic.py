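"""Seeded synthetic sealing zones with exported ground truth.

The generator emulates the statistical structure of super-resolution images of
the osteoclast sealing zone so that every analysis stage has a no-download
test surface:

* **Layout** — a Matérn-style parent–child point process: islet centers are
  placed uniformly with a minimum-separation repulsion, member cores are drawn
  uniformly inside each islet disc, and candidates violating a hard-core
  minimum spacing are rejected and resampled.  This reproduces both the
  islet clustering and the observed minimum core spacing (~400 nm first
  neighbors, ~100 nm core radii).
* **Rendering** — each actin core is a uniform disc of its nominal radius
  convolved with an isotropic Gaussian PSF, on a diffuse background, with
  Poisson shot noise plus additive Gaussian read noise.  The disc model makes
  the gradient (Find-Edges) maximum of a radial profile sit at the nominal
  radius, so the radius estimator and the generator are self-consistent.
  A pure-Gaussian spot model (HWHM = radius) is available for closed-form
  intensity-mass checks.
* **Dynamics** — per-core intensities oscillate as sums of sinusoids
  (defaults near 0.01/0.04/0.15 Hz) whose phases are shared per islet,
  independent per core, or global, emulating locally synchronized actin
  fluctuations at a 2.4 s cadence.
* **Localizations** — 3-D single-molecule clouds with protein-specific
  lateral placement (core-centered, ring at an offset, or islet border) and
  absolute heights blurred by the localization precision, with an optional
  height slope toward the cell interior.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ncx2

from .core import Image2D, ImageStack

__all__ = [
    "LayoutParams", "GroundTruthLayout", "OscSpec", "ProteinSpec",
    "TruthSignals", "PackingError",
    "make_layout", "render_frame", "simulate_movie", "simulate_localizations",
]

DEFAULT_PIXEL_SIZE_NM = 32.25   # reconstruction pixel at 100x magnification
DEFAULT_PSF_SIGMA_NM = 42.5     # ~100 nm FWHM lateral resolution


class PackingError(ValueError):
    """Requested core density cannot satisfy the hard-core constraint."""


@dataclasses.dataclass
class LayoutParams:
    """Parameters of the islet-clustered core layout.

    Defaults mirror the measured sealing-zone geometry: ~100 nm core radii,
    islets of a few um^2 holding ~7 cores each, and a hard-core spacing that
    yields first neighbors in the 400-700 nm range.
    """

    field_size_nm: tuple[float, float] = (10000.0, 10000.0)  # (width, height)
    n_islets: int = 8
    islet_radius_nm: float = 850.0
    cores_per_islet_mean: float = 7.0
    hard_core_nm: float = 300.0
    core_radius_nm_mean: float = 100.0
    core_radius_nm_sd: float = 15.0
    base_intensity_mean: float = 50.0
    base_intensity_sd: float = 8.0
    islet_min_separation_nm: float | None = None  # default: 2.5 * islet_radius_nm
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size_nm
        if not (w > 0 and h > 0 and self.islet_radius_nm > 0
                and self.core_radius_nm_mean > 0 and self.hard_core_nm > 0):
            raise ValueError("all lengths must be positive")
        if self.hard_core_nm >= 2 * self.islet_radius_nm:
            raise ValueError("hard_core_nm must be < 2 * islet_radius_nm")
        if self.n_islets < 0 or self.cores_per_islet_mean < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def islet_separation_nm(self) -> float:
        if self.islet_min_separation_nm is not None:
            return self.islet_min_separation_nm
        return 2.5 * self.islet_radius_nm


@dataclasses.dataclass
class GroundTruthLayout:
    """Ground-truth islets and cores of a synthetic sealing zone.

    ``cores`` columns: core_id, islet_id, x_nm, y_nm, radius_nm,
    base_intensity.  ``islets`` columns: islet_id, x_nm, y_nm.
    """

    cores: pd.DataFrame
    islets: pd.DataFrame
    field_size_nm: tuple[float, float]
    islet_radius_nm: float
    params: LayoutParams | None = None

    @property
    def coords_nm(self) -> np.ndarray:
        return self.cores[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.cores)

    # --- manifest round-trip ----------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cores.to_csv(path / "cores_truth.csv", index=False)
        self.islets.to_csv(path / "islets_truth.csv", index=False)
        manifest = {
            "field_size_nm": list(self.field_size_nm),
            "islet_radius_nm": self.islet_radius_nm,
            "params": dataclasses.asdict(self.params) if self.params else None,
        }
        (path / "layout_manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "GroundTruthLayout":
        path = Path(path)
        manifest = json.loads((path / "layout_manifest.json").read_text())
        params = None
        if manifest.get("params"):
            p = dict(manifest["params"])
            p["field_size_nm"] = tuple(p["field_size_nm"])
            params = LayoutParams(**p)
        return cls(
            cores=pd.read_csv(path / "cores_truth.csv"),
            islets=pd.read_csv(path / "islets_truth.csv"),
            field_size_nm=tuple(manifest["field_size_nm"]),
            islet_radius_nm=float(manifest["islet_radius_nm"]),
            params=params,
        )


@dataclasses.dataclass
class OscSpec:
    """Sum-of-sinusoids model of per-core actin-content oscillations."""

    components: Sequence[tuple[float, float]] = ((0.01, 0.12), (0.04, 0.12),
                                                 (0.15, 0.12))
    phase_model: Literal["islet_shared", "independent", "global"] = "islet_shared"
    noise_sd_fraction: float = 0.02
    dt_s: float = 2.4
    n_frames: int = 67  # ~160 s at 2.4 s intervals

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        nyquist = 1.0 / (2.0 * self.dt_s)
        for f, a in self.components:
            if not (0 < f < nyquist):
                raise ValueError(f"frequency {f} Hz not below Nyquist {nyquist} Hz")
            if not (0 <= a < 1):
                raise ValueError("amplitude fractions must be in [0, 1)")
        if self.phase_model not in ("islet_shared", "independent", "global"):
            raise ValueError(f"unknown phase model {self.phase_model!r}")


@dataclasses.dataclass
class ProteinSpec:
    """Lateral and axial placement model for one protein species."""

    name: str
    lateral_model: Literal["core_centered", "ring_at_offset_nm",
                           "islet_border"] = "core_centered"
    ring_offset_nm: float = 0.0
    axial_mean_nm: float = 100.0
    axial_slope_nm_per_um: float = 0.0
    localization_precision_nm: float = 15.0
    lateral_jitter_nm: float = 30.0

    def __post_init__(self) -> None:
        if self.localization_precision_nm <= 0:
            raise ValueError("localization precision must be positive")
        if self.axial_mean_nm < 0:
            raise ValueError("axial_mean_nm must be >= 0")


@dataclasses.dataclass
class TruthSignals:
    """Exact noiseless per-core intensity traces for a simulated movie."""

    core_ids: np.ndarray
    islet_ids: np.ndarray
    times_s: np.ndarray
    signals: np.ndarray          # (n_cores, T), noiseless, clamped at 0
    clamped: np.ndarray          # (n_cores,) bool: any frame clamped
    phases: np.ndarray           # (n_cores, n_components)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.signals,
                          columns=[f"t{j}" for j in range(self.signals.shape[1])])
        df.insert(0, "core_id", self.core_ids)
        df.insert(1, "islet_id", self.islet_ids)
        df.insert(2, "clamped", self.clamped)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layout

def make_layout(params: LayoutParams) -> GroundTruthLayout:
    """Draw an islet-clustered core layout with hard-core rejection.

    Islet centers are placed by dart throwing with a minimum separation;
    member core counts are Poisson with mean ``cores_per_islet_mean`` and
    positions uniform in the islet disc, rejected (bounded retries) if they
    violate ``hard_core_nm`` against any already-placed core or fall outside
    the field.

    Raises
    ------
    PackingError
        If the expected hard-core disc area exceeds ~60% of the field, i.e.
        the requested density is unsatisfiable.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.field_size_nm
    expected = params.n_islets * params.cores_per_islet_mean
    if expected * np.pi * params.hard_core_nm ** 2 > 0.6 * w * h:
        raise PackingError(
            f"expected {expected:.0f} cores with hard core {params.hard_core_nm} nm "
            f"cannot pack into a {w:.0f} x {h:.0f} nm field")

    margin = min(params.islet_radius_nm, w / 2, h / 2)
    centers: list[np.ndarray] = []
    for _ in range(params.n_islets):
        for _attempt in range(1000):
            p = rng.uniform([margin, margin], [w - margin, h - margin])
            if all(np.hypot(*(p - q)) >= params.islet_separation_nm
                   for q in centers):
                centers.append(p)
                break
        else:
            raise PackingError(
                f"could not place {params.n_islets} islet centers with "
                f"separation {params.islet_separation_nm:.0f} nm")

    rows = []
    placed: list[np.ndarray] = []
    core_id = 0
    for islet_id, cen in enumerate(centers):
        n_members = rng.poisson(params.cores_per_islet_mean)
        for _ in range(n_members):
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = params.islet_radius_nm * np.sqrt(rng.uniform())
                p = cen + rad * np.array([np.cos(ang), np.sin(ang)])
                if not (0 <= p[0] <= w and 0 <= p[1] <= h):
                    continue
                if all(np.hypot(*(p - q)) >= params.hard_core_nm for q in placed):
                    placed.append(p)
                    radius = float(np.clip(
                        rng.normal(params.core_radius_nm_mean,
                                   params.core_radius_nm_sd), 20.0, 1000.0))
                    base = float(max(rng.normal(params.base_intensity_mean,
                                                params.base_intensity_sd), 1.0))
                    rows.append((core_id, islet_id, p[0], p[1], radius, base))
                    core_id += 1
                    break
            # unplaceable member after bounded retries: dropped

    cores = pd.DataFrame(rows, columns=["core_id", "islet_id", "x_nm", "y_nm",
                                        "radius_nm", "base_intensity"])
    if not rows:
        cores = cores.astype({"core_id": int, "islet_id": int})
    islets = pd.DataFrame({
        "islet_id": np.arange(len(centers)),
        "x_nm": [c[0] for c in centers],
        "y_nm": [c[1] for c in centers],
    })
    return GroundTruthLayout(cores, islets, (w, h), params.islet_radius_nm,
                             params)


# ---------------------------------------------------------------------------
# rendering

def _disc_profile(rho_nm: np.ndarray, radius_nm: float,
                  psf_sigma_nm: float) -> np.ndarray:
    """Radial profile of a unit-amplitude uniform disc blurred by the PSF.

    The convolution of a disc indicator with an isotropic Gaussian equals the
    probability that a 2-D normal deviate centered at distance ``rho`` lands
    inside the disc, i.e. a noncentral chi-square CDF with 2 dof.
    """
    s2 = psf_sigma_nm ** 2
    return ncx2.cdf(radius_nm ** 2 / s2, 2, rho_nm ** 2 / s2)


def _gaussian_profile(rho_nm: np.ndarray, radius_nm: float,
                      psf_sigma_nm: float) -> np.ndarray:
    # spot sigma chosen so the intensity half-width at half-maximum equals
    # the nominal radius; PSF blur adds in quadrature
    sigma = np.hypot(radius_nm / np.sqrt(2 * np.log(2)), psf_sigma_nm)
    return np.exp(-rho_nm ** 2 / (2 * sigma ** 2))


def _annulus_profile(rho_nm: np.ndarray, ring_radius_nm: float,
                     width_sigma_nm: float) -> np.ndarray:
    return np.exp(-(rho_nm - ring_radius_nm) ** 2 / (2 * width_sigma_nm ** 2))


def _spot_patches(layout: GroundTruthLayout, channel, pixel_size_nm: float,
                  psf_sigma_nm: float, spot_model: str):
    """Precompute one unit-amplitude patch per source (core or islet).

    Returns a list of ``(row_slice, col_slice, patch, amplitude, source_id)``
    against an image of the layout's field size.
    """
    w, h = layout.field_size_nm
    n_cols = max(int(round(w / pixel_size_nm)), 1)
    n_rows = max(int(round(h / pixel_size_nm)), 1)

    if isinstance(channel, ProteinSpec) and channel.lateral_model == "islet_border":
        sources = [(int(r.islet_id), r.x_nm, r.y_nm, layout.islet_radius_nm, 1.0)
                   for r in layout.islets.itertuples()]
    else:
        sources = [(int(r.core_id), r.x_nm, r.y_nm, r.radius_nm, r.base_intensity)
                   for r in layout.cores.itertuples()]

    patches = []
    for sid, x, y, radius, base in sources:
        if isinstance(channel, ProteinSpec):
            if channel.lateral_model == "core_centered":
                extent = radius + 4 * psf_sigma_nm
                profile = lambda rho, r=radius: _gaussian_profile(rho, r, psf_sigma_nm)
            elif channel.lateral_model == "ring_at_offset_nm":
                ring = radius + channel.ring_offset_nm
                width = max(channel.lateral_jitter_nm, psf_sigma_nm)
                extent = ring + 4 * width
                profile = lambda rho, rr=ring, ww=width: _annulus_profile(rho, rr, ww)
            else:  # islet_border
                ring = radius  # islet radius for islet sources
                width = max(75.0, psf_sigma_nm)
                extent = ring + 4 * width
                profile = lambda rho, rr=ring, ww=width: _annulus_profile(rho, rr, ww)
        elif spot_model == "disc":
            extent = radius + 5 * psf_sigma_nm
            profile = lambda rho, r=radius: _disc_profile(rho, r, psf_sigma_nm)
        elif spot_model == "gaussian":
            extent = 5 * np.hypot(radius / np.sqrt(2 * np.log(2)), psf_sigma_nm)
            profile = lambda rho, r=radius: _gaussian_profile(rho, r, psf_sigma_nm)
        else:
            raise ValueError(f"unknown spot model {spot_model!r}")

        cx, cy = x / pixel_size_nm, y / pixel_size_nm
        # pixel (i, j) covers [j - 0.5, j + 0.5] * ps, so the image extends
        # half a pixel beyond the outermost pixel centers
        if not (-0.5 <= cx <= n_cols - 0.5 and -0.5 <= cy <= n_rows - 0.5):
            raise ValueError(
                f"source {sid} at ({x:.0f}, {y:.0f}) nm lies outside the "
                f"{n_cols} x {n_rows} px image")
        half = int(np.ceil(extent / pixel_size_nm)) + 1
        r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, n_rows)
        c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, n_cols)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rho = np.hypot((cc - cx), (rr - cy)) * pixel_size_nm
        patches.append((slice(r0, r1), slice(c0, c1), profile(rho), base, sid))
    return (n_rows, n_cols), patches


def render_frame(layout: GroundTruthLayout,
                 channel: ProteinSpec | str = "actin",
                 pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                 psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
                 background: float = 40.0,
                 read_noise_sd: float = 3.0,
                 noise: bool = True,
                 spot_model: Literal["disc", "gaussian"] = "disc",
                 intensity_scale: np.ndarray | None = None,
                 rng: np.random.Generator | int | None = None) -> Image2D:
    """Render one calibrated frame of a layout.

    ``channel="actin"`` renders each core as a blurred disc (or Gaussian)
    spot with peak amplitude ``base_intensity``; a :class:`ProteinSpec`
    renders core-centered spots, rings around cores, or annuli around islet
    hulls.  ``intensity_scale`` (per-core) multiplies the base amplitudes —
    used by :func:`simulate_movie`.  Noise is Poisson shot noise on the
    expected image plus Gaussian read noise; defaults give a peak SNR of ~5.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    (n_rows, n_cols), patches = _spot_patches(layout, channel, pixel_size_nm,
                                              psf_sigma_nm, spot_model)
    img = np.full((n_rows, n_cols), float(background))
    scale = {}
    if intensity_scale is not None:
        ids = layout.cores["core_id"].to_numpy()
        scale = dict(zip(ids, np.asarray(intensity_scale, dtype=float)))
    for rs, cs, patch, base, sid in patches:
        img[rs, cs] += patch * (scale.get(sid, base) if scale else base)
    if noise:
        rng = np.random.default_rng(rng)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if read_noise_sd > 0:
            img += rng.normal(0.0, read_noise_sd, img.shape)
        img = np.clip(img, 0, None)
    label = channel.name if isinstance(channel, ProteinSpec) else str(channel)
    return Image2D(img, pixel_size_nm, label)


# ---------------------------------------------------------------------------
# movies

def simulate_movie(layout: GroundTruthLayout, osc: OscSpec,
                   pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                   psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
                   background: float = 40.0,
                   read_noise_sd: float = 3.0,
                   noise: bool = True,
                   spot_model: Literal["disc", "gaussian"] = "disc",
                   rng: np.random.Generator | int | None = None,
                   ) -> tuple[ImageStack, TruthSignals]:
    """Render a time-lapse of oscillating cores plus the exact truth signals.

    Per-core intensity follows
    ``I_i(t) = base_i * (1 + sum_k a_k sin(2 pi f_k t + phi_{g(i),k}))``
    with phases shared per islet (``islet_shared``), independent per core, or
    global.  ``TruthSignals`` stores the exact noiseless traces; rendered
    frames add the generator's multiplicative amplitude noise and the imaging
    noise model of :func:`render_frame`.  Negative intensities are clamped to
    zero and flagged.
    """
    rng = np.random.default_rng(rng)
    cores = layout.cores
    n = len(cores)
    t = np.arange(osc.n_frames) * osc.dt_s
    comps = list(osc.components)
    islet_ids = cores["islet_id"].to_numpy()

    phases = np.zeros((n, len(comps)))
    for k in range(len(comps)):
        if osc.phase_model == "global":
            phases[:, k] = rng.uniform(0, 2 * np.pi)
        elif osc.phase_model == "islet_shared":
            per_islet = {i: rng.uniform(0, 2 * np.pi)
                         for i in np.unique(islet_ids)}
            phases[:, k] = [per_islet[i] for i in islet_ids]
        else:
            phases[:, k] = rng.uniform(0, 2 * np.pi, n)

    base = cores["base_intensity"].to_numpy(dtype=float)[:, None]
    mod = np.ones((n, osc.n_frames))
    for k, (f, a) in enumerate(comps):
        mod += a * np.sin(2 * np.pi * f * t[None, :] + phases[:, k][:, None])
    truth = base * mod
    clamped = (truth < 0).any(axis=1)
    truth = np.clip(truth, 0.0, None)

    amplitudes = truth.copy()
    if osc.noise_sd_fraction > 0:
        amplitudes = np.clip(
            truth + rng.normal(0.0, osc.noise_sd_fraction, truth.shape) * base,
            0.0, None)

    # patches are geometry-only, so render them once and scale per frame
    (n_rows, n_cols), patches = _spot_patches(layout, "actin", pixel_size_nm,
                                              psf_sigma_nm, spot_model)
    id_to_row = {cid: i for i, cid in enumerate(cores["core_id"].to_numpy())}
    frames = np.empty((osc.n_frames, n_rows, n_cols))
    for j in range(osc.n_frames):
        img = np.full((n_rows, n_cols), float(background))
        for rs, cs, patch, _base, sid in patches:
            img[rs, cs] += patch * amplitudes[id_to_row[sid], j]
        if noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if read_noise_sd > 0:
                img += rng.normal(0.0, read_noise_sd, img.shape)
            img = np.clip(img, 0, None)
        frames[j] = img

    stack = ImageStack(frames, osc.dt_s, pixel_size_nm, "actin")
    signals = TruthSignals(cores["core_id"].to_numpy(), islet_ids, t, truth,
                           clamped, phases)
    return stack, signals


# ---------------------------------------------------------------------------
# localizations

def simulate_localizations(layout: GroundTruthLayout, protein: ProteinSpec,
                           n_locs: int,
                           belt_axis: tuple[float, tuple[float, float]] | None = None,
                           cell_id: int = 0,
                           rng: np.random.Generator | int | None = None,
                           ) -> pd.DataFrame:
    """Draw a 3-D localization cloud for one protein species.

    ``belt_axis`` is ``(angle_deg, interior_normal)``; the belt line passes
    through the core centroid.  The signed interior distance of each
    localization (positive toward the cell interior) drives the axial slope:
    ``z ~ Normal(axial_mean + slope * d_um, precision)``.  Lateral positions
    follow the protein's lateral model and are blurred by the localization
    precision.

    Returns a table with columns ``x_nm, y_nm, z_nm, protein, cell`` plus
    ground-truth columns ``true_source_id`` and ``true_interior_nm``.
    """
    if n_locs <= 0:
        raise ValueError("n_locs must be positive")
    rng = np.random.default_rng(rng)
    cores = layout.cores
    if len(cores) == 0:
        raise ValueError("layout has no cores")

    if belt_axis is None:
        angle_deg, normal = 0.0, (0.0, -1.0)
    else:
        angle_deg, normal = belt_axis
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    origin = cores[["x_nm", "y_nm"]].to_numpy().mean(axis=0)

    if protein.lateral_model == "islet_border":
        src = layout.islets[["x_nm", "y_nm"]].to_numpy()
        src_ids = layout.islets["islet_id"].to_numpy()
        radii = np.full(len(src), layout.islet_radius_nm)
    else:
        src = cores[["x_nm", "y_nm"]].to_numpy()
        src_ids = cores["core_id"].to_numpy()
        radii = cores["radius_nm"].to_numpy(dtype=float)

    pick = rng.integers(0, len(src), n_locs)
    centers = src[pick]
    if protein.lateral_model == "core_centered":
        lateral = centers + rng.normal(0.0, radii[pick][:, None], (n_locs, 2))
    else:
        ring = radii[pick] + (protein.ring_offset_nm
                              if protein.lateral_model == "ring_at_offset_nm" else 0.0)
        rho = ring + rng.normal(0.0, protein.lateral_jitter_nm, n_locs)
        ang = rng.uniform(0, 2 * np.pi, n_locs)
        lateral = centers + rho[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])

    interior_nm = (lateral - origin) @ normal
    z = (protein.axial_mean_nm
         + protein.axial_slope_nm_per_um * interior_nm / 1000.0
         + rng.normal(0.0, protein.localization_precision_nm, n_locs))
    xy = lateral + rng.normal(0.0, protein.localization_precision_nm, (n_locs, 2))

    return pd.DataFrame({
        "x_nm": xy[:, 0], "y_nm": xy[:, 1], "z_nm": z,
        "protein": protein.name, "cell": cell_id,
        "true_source_id": src_ids[pick], "true_interior_nm": interior_nm,
    })
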