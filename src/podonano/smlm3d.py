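"""Core-relative signed r-z analysis of 3-D single-molecule localizations.

Localizations (absolute heights above the substrate, ~15 nm precision) are
assigned to rectangular boxes centered on each actin core — 10 um long and
200 nm wide, once along the belt direction and once transverse to it — and
converted to a local (r, z) representation where r is the signed along-axis
distance to the core.  On the transverse axis, r is positive toward the cell
interior and negative toward the exterior.  Profiles bin r in 100 nm classes
up to 1 um from the core and 500 nm classes beyond, with per-cell medians of
z; radial and vertical distributions, per-cell median heights, and an
interior/exterior symmetry index summarize each protein.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoreSet

__all__ = ["BeltGeometry", "RZDistributions", "assign_locs", "bin_rz",
           "rz_bin_edges", "distributions", "symmetry_index",
           "read_localizations"]

LOC_COLUMNS = ("x_nm", "y_nm", "z_nm", "protein", "cell")


def read_localizations(path, column_map: dict[str, str] | None = None,
                       ) -> pd.DataFrame:
    """Read a localization table from CSV with an optional column mapping.

    ``column_map`` maps the file's column names onto the canonical
    ``x_nm, y_nm, z_nm, protein, cell``; missing ``protein``/``cell`` columns
    default to ``""`` / 0.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col, default in (("protein", ""), ("cell", 0)):
        if col not in df.columns:
            df[col] = default
    missing = [c for c in ("x_nm", "y_nm", "z_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization table missing columns {missing}")
    if not np.isfinite(df[["x_nm", "y_nm", "z_nm"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in localization table")
    return df


class BeltGeometry:
    """Per-cell belt orientation and interior side.

    Each cell maps to ``(angle_deg, interior_normal)``: the belt axis angle
    to the horizontal, and the unit normal pointing toward the cell interior
    (must be perpendicular to the axis).
    """

    def __init__(self, entries: dict | None = None):
        self._entries: dict = {}
        if entries:
            for cell, (angle, normal) in entries.items():
                self.add(cell, angle, normal)

    def add(self, cell, angle_deg: float, interior_normal) -> None:
        n = np.asarray(interior_normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"cell {cell}: interior normal must be unit length")
        axis = np.array([np.cos(np.deg2rad(angle_deg)),
                         np.sin(np.deg2rad(angle_deg))])
        if abs(float(axis @ n)) > 1e-6:
            raise ValueError(
                f"cell {cell}: interior normal must be perpendicular to the axis")
        self._entries[cell] = (float(angle_deg), n)

    @classmethod
    def from_angle(cls, cell, angle_deg: float,
                   interior_sign: int = +1) -> "BeltGeometry":
        """Single-cell geometry; ``interior_sign=+1`` puts the interior on
        the ``(-sin, cos)`` side of the axis."""
        n = interior_sign * np.array([-np.sin(np.deg2rad(angle_deg)),
                                      np.cos(np.deg2rad(angle_deg))])
        return cls({cell: (angle_deg, n)})

    def cells(self):
        return list(self._entries)

    def __contains__(self, cell) -> bool:
        return cell in self._entries

    def __getitem__(self, cell):
        return self._entries[cell]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {str(c): {"angle_deg": a, "interior_normal": list(n)}
             for c, (a, n) in self._entries.items()}, indent=1))

    @classmethod
    def from_json(cls, path) -> "BeltGeometry":
        raw = json.loads(Path(path).read_text())
        geom = cls()
        for cell, entry in raw.items():
            key: object = int(cell) if cell.lstrip("-").isdigit() else cell
            geom.add(key, entry["angle_deg"], entry["interior_normal"])
        return geom


def assign_locs(locs: pd.DataFrame, cores: CoreSet, geom: BeltGeometry,
                box_length_nm: float = 10000.0,
                box_width_nm: float = 200.0) -> pd.DataFrame:
    """Assign localizations to per-core oriented boxes in signed r-z space.

    For each core and each of the two axes (``along_belt`` = belt direction,
    ``transverse`` = interior normal), localizations inside the
    ``box_length_nm x box_width_nm`` rectangle centered on the core get
    ``r`` = signed projection onto the axis.  On the transverse axis, r > 0
    is toward the cell interior; on the along-belt axis the sign follows the
    fixed reference orientation of the axis (interior/exterior is undefined
    there).  A localization inside several cores' boxes is assigned to each;
    cells without belt geometry are skipped with a warning.

    Returns a table with columns ``cell, core_id, axis, r_nm, z_nm,
    loc_index``.
    """
    half_l, half_w = box_length_nm / 2.0, box_width_nm / 2.0
    out = []
    for cell, cell_locs in locs.groupby("cell"):
        if cell not in geom:
            warnings.warn(f"no belt geometry for cell {cell!r}; skipped",
                          stacklevel=2)
            continue
        angle_deg, normal = geom[cell]
        axis_u = np.array([np.cos(np.deg2rad(angle_deg)),
                           np.sin(np.deg2rad(angle_deg))])
        xy = cell_locs[["x_nm", "y_nm"]].to_numpy(dtype=float)
        z = cell_locs["z_nm"].to_numpy(dtype=float)
        loc_idx = cell_locs.index.to_numpy()
        for cid, cx, cy in zip(cores.ids, cores.coords_nm[:, 0],
                               cores.coords_nm[:, 1]):
            d = xy - (cx, cy)
            for axis_name, u in (("along_belt", axis_u),
                                 ("transverse", normal)):
                r = d @ u
                lat = d @ np.array([-u[1], u[0]])
                inside = (np.abs(r) <= half_l) & (np.abs(lat) <= half_w)
                if not inside.any():
                    continue
                out.append(pd.DataFrame({
                    "cell": cell, "core_id": cid, "axis": axis_name,
                    "r_nm": r[inside], "z_nm": z[inside],
                    "loc_index": loc_idx[inside],
                }))
    if not out:
        return pd.DataFrame(columns=["cell", "core_id", "axis", "r_nm",
                                     "z_nm", "loc_index"])
    return pd.concat(out, ignore_index=True)


def rz_bin_edges(inner_bin_nm: float = 100.0, outer_bin_nm: float = 500.0,
                 inner_extent_nm: float = 1000.0,
                 max_extent_nm: float = 5000.0) -> np.ndarray:
    """Signed variable-width bin edges: fine classes near the core
    (|r| < ``inner_extent_nm``), coarse beyond, symmetric about 0."""
    inner = np.arange(-inner_extent_nm, inner_extent_nm + inner_bin_nm / 2,
                      inner_bin_nm)
    neg = np.arange(-max_extent_nm, -inner_extent_nm, outer_bin_nm)
    pos = np.arange(inner_extent_nm + outer_bin_nm,
                    max_extent_nm + outer_bin_nm / 2, outer_bin_nm)
    return np.concatenate([neg, inner, pos])


def bin_rz(points: pd.DataFrame,
           edges: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell median height in signed r classes.

    Bins are half-open ``[low, high)`` (so r = 0 belongs to the first
    interior-side class and r = -1000 to the [-1000, -900) class).  Within
    each bin the data of all of a cell's cores are pooled and the median z
    taken per cell; empty bins are absent from the output (missing, never
    zero).

    Returns columns ``axis, cell, bin_low_nm, bin_high_nm, median_z_nm,
    count``.
    """
    if len(points) == 0:
        raise ValueError("no r-z points to bin")
    if edges is None:
        edges = rz_bin_edges()
    r = points["r_nm"].to_numpy(dtype=float)
    idx = np.digitize(r, edges, right=False) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    pts = points.loc[ok].copy()
    pts["_bin"] = idx[ok]
    rows = []
    for (axis, cell, b), grp in pts.groupby(["axis", "cell", "_bin"]):
        rows.append((axis, cell, edges[b], edges[b + 1],
                     float(grp["z_nm"].median()), len(grp)))
    return pd.DataFrame(rows, columns=["axis", "cell", "bin_low_nm",
                                       "bin_high_nm", "median_z_nm", "count"])


@dataclasses.dataclass
class RZDistributions:
    """Unit-area radial and vertical histograms plus median heights."""

    r_edges_nm: np.ndarray
    r_density: np.ndarray
    z_edges_nm: np.ndarray
    z_density: np.ndarray
    median_z_per_cell: pd.DataFrame    # columns: cell, median_z_nm, n
    median_z_nm: float                 # pooled: median of per-cell medians


def distributions(points: pd.DataFrame, r_bin_nm: float = 100.0,
                  z_bin_nm: float = 20.0) -> RZDistributions:
    """Radial and vertical distributions of assigned localizations.

    Histograms are normalized to unit area.  The pooled median height
    aggregates per-cell medians (median of medians), so unequally sampled
    cells contribute equally.
    """
    if len(points) == 0:
        raise ValueError("no r-z points")
    r = points["r_nm"].to_numpy(dtype=float)
    z = points["z_nm"].to_numpy(dtype=float)

    def _edges(vals, width):
        lo = np.floor(vals.min() / width) * width
        hi = np.ceil(vals.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + width / 2, width)

    r_edges = _edges(r, r_bin_nm)
    z_edges = _edges(z, z_bin_nm)
    r_density, _ = np.histogram(r, bins=r_edges, density=True)
    z_density, _ = np.histogram(z, bins=z_edges, density=True)
    per_cell = points.groupby("cell")["z_nm"].agg(["median", "size"])
    per_cell = per_cell.reset_index().rename(
        columns={"median": "median_z_nm", "size": "n"})
    pooled = float(per_cell["median_z_nm"].median())
    return RZDistributions(r_edges, r_density, z_edges, z_density, per_cell,
                           pooled)


def symmetry_index(points: pd.DataFrame) -> pd.DataFrame:
    """Interior/exterior symmetry index per cell.

    On transverse-axis points with r != 0:
    ``(N_interior - N_exterior) / (N_interior + N_exterior)``, so +1 means
    all molecules sit on the interior side and 0 a perfectly symmetric
    distribution.  Cells whose points all have r = 0 get NaN (undefined).
    """
    trans = points[points["axis"] == "transverse"]
    if len(trans) == 0:
        raise ValueError("no transverse-axis points")
    rows = []
    for cell, grp in trans.groupby("cell"):
        r = grp["r_nm"].to_numpy(dtype=float)
        n_int = int((r > 0).sum())
        n_ext = int((r < 0).sum())
        if n_int + n_ext == 0:
            rows.append((cell, float("nan"), 0, 0))
        else:
            rows.append((cell, (n_int - n_ext) / (n_int + n_ext),
                         n_int, n_ext))
    return pd.DataFrame(rows, columns=["cell", "symmetry_index",
                                       "n_interior", "n_exterior"])
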