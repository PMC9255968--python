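"""Delaunay-tessellation neighbor statistics over core coordinates.

Inter-core spacing in a podosome field is summarized from the Delaunay
triangulation of the core centroids: *direct neighbors* are pairs joined by a
Delaunay edge, and the *first neighbor* of a core is its minimum-length
incident edge.  Edges whose two endpoints both lie on the convex hull are
excluded from all statistics — the tessellation boundary spans the outside of
the point cloud and its edge lengths are not neighbor distances.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .core import CoreSet

__all__ = ["NeighborGraph", "NeighborStats", "DegenerateInputError",
           "build_graph", "direct_neighbor_stats", "nearest_neighbor_stats"]


class DegenerateInputError(ValueError):
    """Fewer than 3 points, or all points collinear."""


@dataclasses.dataclass
class NeighborGraph:
    """Delaunay edges over core centroids with hull-exclusion flags.

    ``edges`` columns: ``i``, ``j`` (vertex indices, i < j), ``length_nm``,
    ``excluded`` (both endpoints on the convex hull).
    """

    points_nm: np.ndarray        # (N, 2)
    ids: np.ndarray              # (N,) vertex ids
    edges: pd.DataFrame
    hull: np.ndarray             # (N,) bool

    @property
    def included_edges(self) -> pd.DataFrame:
        return self.edges[~self.edges["excluded"]]

    def to_csv(self, path) -> None:
        out = self.edges.copy()
        out.insert(0, "id_i", self.ids[out["i"].to_numpy()])
        out.insert(1, "id_j", self.ids[out["j"].to_numpy()])
        out.to_csv(path, index=False)


def build_graph(cores: CoreSet | np.ndarray) -> NeighborGraph:
    """Delaunay triangulation of core centroids with hull-hull edge exclusion.

    Raises :class:`DegenerateInputError` for fewer than 3 points or a
    collinear point set.  Cocircular degeneracies are broken by the
    triangulator's symbolic perturbation (deterministic per input).
    """
    if isinstance(cores, CoreSet):
        pts = cores.coords_nm
        ids = cores.ids
    else:
        pts = np.asarray(cores, dtype=float)
        ids = np.arange(len(pts))
    if len(pts) < 3:
        raise DegenerateInputError(f"need >= 3 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
        hull_idx = ConvexHull(pts).vertices
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateInputError("points are collinear")

    pairs = set()
    for simplex in tri.simplices:
        a, b, c = sorted(int(v) for v in simplex)
        pairs.update({(a, b), (a, c), (b, c)})
    edge_arr = np.array(sorted(pairs), dtype=int)
    lengths = np.hypot(*(pts[edge_arr[:, 0]] - pts[edge_arr[:, 1]]).T)

    hull = np.zeros(len(pts), dtype=bool)
    hull[hull_idx] = True
    excluded = hull[edge_arr[:, 0]] & hull[edge_arr[:, 1]]

    edges = pd.DataFrame({"i": edge_arr[:, 0], "j": edge_arr[:, 1],
                          "length_nm": lengths, "excluded": excluded})
    return NeighborGraph(pts, np.asarray(ids), edges, hull)


@dataclasses.dataclass
class NeighborStats:
    """Per-vertex neighbor-distance summary plus the pooled distribution.

    ``per_vertex`` columns: ``vertex``, ``id``, ``value_nm`` (NaN when the
    vertex has no included incident edge), ``n_edges``.
    """

    per_vertex: pd.DataFrame
    pooled_nm: np.ndarray
    pooled_median_nm: float
    statistic: str

    def histogram(self, bin_width_nm: float = 100.0):
        """Counts-conserving histogram of the pooled values."""
        if self.pooled_nm.size == 0:
            return np.array([]), np.array([0.0])
        top = np.ceil(self.pooled_nm.max() / bin_width_nm) * bin_width_nm
        edges = np.arange(0.0, top + bin_width_nm, bin_width_nm)
        counts, edges = np.histogram(self.pooled_nm, bins=edges)
        return counts, edges


def _incident_stats(graph: NeighborGraph, reducer, statistic: str,
                    pooled_mode: str) -> NeighborStats:
    inc = graph.included_edges
    if len(inc) == 0:
        warnings.warn("graph has no included (non hull-hull) edges",
                      stacklevel=3)
    n = len(graph.points_nm)
    values = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    by_vertex: dict[int, list[float]] = {v: [] for v in range(n)}
    for i, j, length in inc[["i", "j", "length_nm"]].itertuples(index=False):
        by_vertex[int(i)].append(length)
        by_vertex[int(j)].append(length)
    for v, lengths in by_vertex.items():
        counts[v] = len(lengths)
        if lengths:
            values[v] = reducer(lengths)

    if pooled_mode == "edges":
        pooled = inc["length_nm"].to_numpy()
    else:  # per-vertex values
        pooled = values[np.isfinite(values)]
    per_vertex = pd.DataFrame({"vertex": np.arange(n), "id": graph.ids,
                               "value_nm": values, "n_edges": counts})
    median = float(np.median(pooled)) if pooled.size else float("nan")
    return NeighborStats(per_vertex, pooled, median, statistic)


def direct_neighbor_stats(graph: NeighborGraph) -> NeighborStats:
    """Per-vertex mean included-edge length and the pooled edge lengths.

    The headline summary is the pooled edge-length median (each included
    Delaunay edge counted once); the per-vertex means are also reported since
    published figures use either convention.
    """
    return _incident_stats(graph, lambda v: float(np.mean(v)),
                           "direct_neighbor_mean", pooled_mode="edges")


def nearest_neighbor_stats(graph: NeighborGraph) -> NeighborStats:
    """Per-vertex minimum included-edge length (first-neighbor distance).

    For interior (non-hull) vertices this equals the global nearest-neighbor
    distance, since the nearest neighbor of a point is always joined to it by
    a Delaunay edge.  The pooled distribution collects the per-vertex minima.
    """
    return _incident_stats(graph, lambda v: float(np.min(v)),
                           "nearest_neighbor", pooled_mode="vertices")
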