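"""Independent brute-force oracles used to grade the implementation.

These deliberately avoid the library code paths (and scipy.spatial): the
Delaunay oracle enumerates all point triples and tests the empty-circumcircle
property directly, the hull oracle tests all directed pairs, and the box
oracle does explicit rotated-rectangle geometry per localization.
"""

from __future__ import annotations

import numpy as np


def brute_force_delaunay_edges(points: np.ndarray, eps: float = 1e-9) -> set:
    """Edge set of the Delaunay triangulation by empty-circumcircle testing.

    For every triple (i, j, k), compute the circumcircle and accept the
    triangle iff no other point lies strictly inside; the union of accepted
    triangle edges is the Delaunay edge set (general-position inputs).
    """
    n = len(points)
    edges: set = set()
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                a, b, c = points[i], points[j], points[k]
                d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1])
                         + c[0] * (a[1] - b[1]))
                if abs(d) < eps:
                    continue  # collinear triple
                ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
                      + (c @ c) * (a[1] - b[1])) / d
                uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
                      + (c @ c) * (b[0] - a[0])) / d
                center = np.array([ux, uy])
                r2 = (a - center) @ (a - center)
                dists2 = np.einsum("ij,ij->i", points - center, points - center)
                inside = dists2 < r2 * (1 - 1e-12) - eps
                inside[[i, j, k]] = False
                if not inside.any():
                    edges.update({(i, j), (i, k), (j, k)})
    return edges


def brute_force_hull_vertices(points: np.ndarray, eps: float = 1e-9) -> set:
    """Convex-hull vertex set by testing all directed edges.

    (i, j) is a hull edge iff every other point lies on one side of the line
    through i and j; both endpoints of any hull edge are hull vertices.
    """
    n = len(points)
    hull: set = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            rel = points - points[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.ones(n, bool)
            others[[i, j]] = False
            if (cross[others] >= -eps).all() or (cross[others] <= eps).all():
                hull.update({i, j})
    return hull


def brute_force_nearest_neighbor(points: np.ndarray) -> np.ndarray:
    """Global nearest-neighbor distance per point, all-pairs."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_min_pair_distance(points: np.ndarray) -> float:
    """Minimum over all pairwise distances (O(n^2))."""
    best = np.inf
    for i in range(len(points) - 1):
        for j in range(i + 1, len(points)):
            best = min(best, float(np.hypot(*(points[i] - points[j]))))
    return best


def brute_force_box_assignment(locs_xy: np.ndarray, z: np.ndarray,
                               core_xy: np.ndarray, axis_unit: np.ndarray,
                               half_length: float, half_width: float):
    """Per-localization rotated-rectangle membership and signed projection.

    Returns ``(indices, r)`` for localizations inside the box centered on
    the core with its long axis along ``axis_unit``.
    """
    u = np.asarray(axis_unit, float)
    v = np.array([-u[1], u[0]])
    idx, rs = [], []
    for m in range(len(locs_xy)):
        d = locs_xy[m] - core_xy
        r = float(d @ u)
        lat = float(d @ v)
        if abs(r) <= half_length and abs(lat) <= half_width:
            idx.append(m)
            rs.append(r)
    return np.array(idx, int), np.array(rs)
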