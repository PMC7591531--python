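"""Per-cell geometry from Voronoi tessellation of nuclear centroids.

In a confluent layer the Voronoi cell of each nuclear centroid proxies
the cell footprint.  Each cell's polygon is the intersection of the
bisector half-planes against its Voronoi neighbors, clipped to the
analysis domain; area, perimeter and the second-moment-ellipse aspect
ratio are computed analytically from the polygon.  Cells whose polygon
touches the domain (or free) boundary are flagged so they can be
excluded from shape statistics near the open edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi


@dataclass
class CellPolygon:
    """Convex Voronoi cell of one nucleus, with shape metrics."""

    cell_id: int
    vertices: np.ndarray          # (k, 2), counter-clockwise
    area: float
    perimeter: float
    aspect_ratio: float
    is_boundary: bool


def _clip_halfplane(poly: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Clip convex polygon to the half-plane of points closer to p than q.

    Sutherland-Hodgman against the perpendicular bisector of segment pq.
    """
    n = q - p
    m = 0.5 * (p + q)
    # keep x with (x - m) . n <= 0
    d = (poly - m) @ n
    out = []
    k = len(poly)
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        da, db = d[i], d[(i + 1) % k]
        if da <= 0:
            out.append(a)
        if (da < 0) != (db < 0) and da != db:
            t = da / (da - db)
            out.append(a + t * (b - a))
    return np.array(out) if out else np.empty((0, 2))


def polygon_moments(vertices: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Signed area, perimeter, and central second-moment (covariance) matrix.

    Uses the standard shoelace-style closed forms for a simple polygon;
    the covariance is the second central moment of the uniform density
    over the polygon, i.e. central inertia divided by area.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        return 0.0, 0.0, np.zeros((2, 2))
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    ixx = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    iyy = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # central moments per unit area
    cov = np.array([
        [iyy / area - cx * cx, ixy / area - cx * cy],
        [ixy / area - cx * cy, ixx / area - cy * cy],
    ])
    perimeter = float(np.hypot(xn - x, yn - y).sum())
    return float(area), perimeter, cov


def shape_metrics(vertices: np.ndarray) -> tuple[float, float, float]:
    """(area, perimeter, aspect_ratio) of a simple polygon.

    Aspect ratio is major/minor axis of the ellipse sharing the polygon's
    second central moments: sqrt of the covariance eigenvalue ratio.
    Degenerate (zero-area) polygons return area 0 and NaN aspect.
    """
    area, perimeter, cov = polygon_moments(vertices)
    area = abs(area)
    if area <= 0:
        return 0.0, perimeter, float("nan")
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0:
        return area, perimeter, float("inf")
    return area, perimeter, float(np.sqrt(evals[1] / evals[0]))


def tessellate(
    centroids: np.ndarray,
    domain_bounds: tuple[float, float, float, float],
    boundary_tol: float = 1e-9,
) -> list[CellPolygon]:
    """Voronoi cells of nuclear centroids, clipped to a rectangular domain.

    Parameters
    ----------
    centroids : (n, 2) array
        Nuclear centroid positions (µm); n >= 3, non-collinear, unique.
    domain_bounds : (xmin, ymin, xmax, ymax)
        Clip rectangle (image or layer extent).

    Each cell is built by clipping the domain rectangle against the
    perpendicular bisectors of the cell's Voronoi ridge neighbors, which
    handles unbounded edge regions exactly.  Cells touching the domain
    rectangle are flagged ``is_boundary``.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 two-dimensional centroids")
    # duplicate detection
    order = np.lexsort(pts.T)
    eq = np.all(np.isclose(pts[order[1:]], pts[order[:-1]]), axis=1)
    if eq.any():
        dup_ids = sorted(set(order[1:][eq]) | set(order[:-1][eq]))
        raise ValueError(f"duplicate centroids for ids {dup_ids}")
    xmin, ymin, xmax, ymax = domain_bounds
    box = np.array([[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]], float)

    vor = Voronoi(pts)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(pts))}
    for (i, j) in vor.ridge_points:
        neighbors[i].append(j)
        neighbors[j].append(i)

    cells: list[CellPolygon] = []
    for i in range(len(pts)):
        poly = box
        for j in neighbors[i]:
            poly = _clip_halfplane(poly, pts[i], pts[j])
            if len(poly) == 0:
                break
        if len(poly) < 3:
            cells.append(CellPolygon(i, np.empty((0, 2)), 0.0, 0.0, float("nan"), True))
            continue
        area, perim, aspect = shape_metrics(poly)
        on_edge = bool(
            np.any(poly[:, 0] <= xmin + boundary_tol)
            or np.any(poly[:, 0] >= xmax - boundary_tol)
            or np.any(poly[:, 1] <= ymin + boundary_tol)
            or np.any(poly[:, 1] >= ymax - boundary_tol)
        )
        cells.append(CellPolygon(i, poly, area, perim, aspect, on_edge))
    return cells


def morphology_table(cells: list[CellPolygon]) -> pd.DataFrame:
    """Tidy per-cell table of Voronoi shape metrics.

    Includes the dimensionless shape index perimeter/sqrt(area) as a
    derived column.
    """
    rows = [
        (c.cell_id, c.area, c.perimeter, c.aspect_ratio,
         c.perimeter / np.sqrt(c.area) if c.area > 0 else np.nan, c.is_boundary)
        for c in cells
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "area", "perimeter", "aspect_ratio",
                 "shape_index", "is_boundary"],
    )
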