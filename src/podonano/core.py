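"""Calibrated image containers and tabular core sets.

Conventions used throughout the package:

* All lengths are in nanometres, all times in seconds, areas in um^2 at
  interfaces.
* Image arrays are indexed ``[row, column]`` = ``[y, x]``.  The origin of the
  nm coordinate frame is the *center* of pixel ``(0, 0)``; x increases
  rightward (columns), y downward (rows).  A point at ``(x_nm, y_nm)``
  therefore sits at fractional pixel ``(x_nm / pixel_size_nm,
  y_nm / pixel_size_nm)``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["Image2D", "ImageStack", "CoreSet"]


@dataclasses.dataclass
class Image2D:
    """A single-channel 2-D image with a physical pixel size.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of finite intensities.
    pixel_size_nm
        Edge length of one pixel in nanometres (must be positive).
    channel_label
        Free-form channel name (e.g. ``"actin"`` or ``"vinculin"``).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D expects a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be positive")
        self.pixel_size_nm = float(self.pixel_size_nm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height_nm(self) -> float:
        return self.pixels.shape[0] * self.pixel_size_nm

    @property
    def width_nm(self) -> float:
        return self.pixels.shape[1] * self.pixel_size_nm

    def nm_to_px(self, xy_nm: np.ndarray) -> np.ndarray:
        """Convert ``(..., 2)`` nm coordinates (x, y) to fractional pixels."""
        return np.asarray(xy_nm, dtype=float) / self.pixel_size_nm

    def contains_nm(self, x_nm: float, y_nm: float) -> bool:
        """Whether a point lies within the pixel-center bounding box."""
        h, w = self.pixels.shape
        px, py = x_nm / self.pixel_size_nm, y_nm / self.pixel_size_nm
        return 0 <= px <= w - 1 and 0 <= py <= h - 1

    # --- I/O ---------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(
            path,
            self.pixels.astype(np.float32),
            metadata={
                "pixel_size_nm": self.pixel_size_nm,
                "channel_label": self.channel_label,
            },
        )
        _write_sidecar(path, pixel_size_nm=self.pixel_size_nm,
                       channel_label=self.channel_label)

    @classmethod
    def from_tiff(cls, path: str | Path,
                  pixel_size_nm: float | None = None) -> "Image2D":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = _shaped_metadata(tif)
        meta.update(_read_sidecar(path))
        ps = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
        if ps is None:
            raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size_nm")
        return cls(np.asarray(data, dtype=float), float(ps),
                   str(meta.get("channel_label", "")))


@dataclasses.dataclass
class ImageStack:
    """A time-lapse stack ``(T, H, W)`` with pixel size and frame interval."""

    frames: np.ndarray
    dt_s: float
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack expects a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("ImageStack needs at least 2 frames")
        if not (self.dt_s > 0):
            raise ValueError("dt_s must be positive")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s

    def frame(self, t: int) -> Image2D:
        return Image2D(self.frames[t], self.pixel_size_nm, self.channel_label)

    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(
            path,
            self.frames.astype(np.float32),
            photometric="minisblack",
            metadata={
                "pixel_size_nm": self.pixel_size_nm,
                "dt_s": self.dt_s,
                "channel_label": self.channel_label,
            },
        )
        _write_sidecar(path, pixel_size_nm=self.pixel_size_nm, dt_s=self.dt_s,
                       channel_label=self.channel_label)

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size_nm: float | None = None,
                  dt_s: float | None = None) -> "ImageStack":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = _shaped_metadata(tif)
        meta.update(_read_sidecar(path))
        ps = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
        dt = dt_s if dt_s is not None else meta.get("dt_s")
        if ps is None or dt is None:
            raise ValueError(f"{path}: missing calibration; pass pixel_size_nm/dt_s")
        return cls(np.asarray(data, dtype=float), float(dt), float(ps),
                   str(meta.get("channel_label", "")))


_RADIUS_COLS = [f"r_dir_{k}" for k in range(8)]
_CORE_COLS = ["core_id", "x_nm", "y_nm", "peak_intensity", "radius_nm",
              *_RADIUS_COLS, "flags"]


class CoreSet:
    """Detected (or ground-truth) actin cores.

    Thin wrapper around a :class:`pandas.DataFrame` with columns ``core_id``,
    ``x_nm``, ``y_nm`` (intensity-weighted centroids), ``peak_intensity``,
    ``radius_nm`` (NaN until estimated), ``r_dir_0`` .. ``r_dir_7``
    (per-direction radii) and ``flags`` (semicolon-joined strings).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        for col in _CORE_COLS:
            if col not in table.columns:
                table[col] = "" if col == "flags" else np.nan
        if table["core_id"].isna().any():
            table["core_id"] = np.arange(len(table))
        if table["core_id"].duplicated().any():
            raise ValueError("core ids must be unique")
        self.table = table[_CORE_COLS].reset_index(drop=True)

    @classmethod
    def from_arrays(cls, x_nm, y_nm, peak_intensity=None, core_id=None) -> "CoreSet":
        x_nm = np.asarray(x_nm, dtype=float)
        y_nm = np.asarray(y_nm, dtype=float)
        n = len(x_nm)
        return cls(pd.DataFrame({
            "core_id": np.arange(n) if core_id is None else np.asarray(core_id),
            "x_nm": x_nm,
            "y_nm": y_nm,
            "peak_intensity": (np.full(n, np.nan) if peak_intensity is None
                               else np.asarray(peak_intensity, dtype=float)),
        }))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def coords_nm(self) -> np.ndarray:
        """``(N, 2)`` array of (x, y) centroids in nm."""
        return self.table[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def ids(self) -> np.ndarray:
        return self.table["core_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoreSet":
        df = pd.read_csv(path)
        if "flags" in df.columns:
            df["flags"] = df["flags"].fillna("")
        return cls(df)


# --- TIFF metadata helpers -------------------------------------------------

def _shaped_metadata(tif: "tifffile.TiffFile") -> dict:
    meta = {}
    if tif.shaped_metadata:
        for m in tif.shaped_metadata:
            if isinstance(m, dict):
                meta.update(m)
    return meta


def _write_sidecar(path: Path, **fields) -> None:
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(fields, indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        try:
            return json.loads(sidecar.read_text())
        except json.JSONDecodeError:
            return {}
    return {}
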