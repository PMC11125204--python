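"""Geometric measurements on segmented cells and blades.

Per cell: surface area (shoelace on the outline), convex hull, minimal
(minimum-area) bounding rectangle of the hull, and the length-to-width ratio
(LWR) of the rectangle's axes. Per blade (one snapshot): total area as the sum
of living cells' areas, main/secondary axis orientation from second-order area
moments of the union of living cells, and length/width as the extents of the
union projected on those axes.

All measures are invariant under rigid motion; areas scale as c² under uniform
scaling by c. Orientations are reported in degrees modulo 180.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .core import CellOutline, CellStatus, EmbryoSnapshot


@dataclass(frozen=True)
class CellMetrics:
    cell_id: str
    area: float
    lwr: float
    mbr_length: float
    mbr_width: float
    mbr_orientation: float  # degrees in [0, 180)


@dataclass(frozen=True)
class BladeMetrics:
    day: int
    blade_area: float  # Σ area over alive cells (µm²)
    length: float  # extent along main axis (µm)
    width: float  # extent along secondary axis (µm)
    lwr: float
    main_axis_orientation: float  # degrees in [0, 180)
    n_cells_alive: int


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon, independent of winding order.

    Raises ``ValueError`` on degenerate (zero-area or <3 vertex) input.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs >= 3 planar vertices")
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    area = abs(signed)
    scale = max(np.ptp(x), np.ptp(y), 1.0)
    if area <= 1e-12 * scale * scale:
        raise ValueError("degenerate polygon (zero area)")
    return float(area)


def cell_area(outline: CellOutline) -> float:
    return polygon_area(outline.vertices)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull of a point set, collinear-free.

    Raises ``ValueError`` for fewer than 3 points or an all-collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 planar points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate point set (collinear?)") from exc
    return pts[hull.vertices]  # Qhull returns CCW order in 2-D


def min_bounding_rectangle(
    outline: np.ndarray,
) -> tuple[float, float, float, np.ndarray]:
    """Minimum-area enclosing rectangle of a convex outline.

    The minimum-area rectangle has a side collinear with a hull edge, so only
    edge-aligned candidates are scanned (rotating-calipers family).

    Returns ``(length, width, orientation, center)`` with ``length >= width``
    and ``orientation`` the long-axis angle in degrees in ``[0, 180)``. Ties in
    minimal area are broken towards the smaller orientation angle.
    """
    hull = convex_hull(np.asarray(outline, dtype=float))
    edges = np.roll(hull, -1, axis=0) - hull
    angles = np.arctan2(edges[:, 1], edges[:, 0]) % (np.pi / 2.0)
    angles = np.unique(np.round(angles, 12))

    best = None  # (area, orientation_deg, length, width, center)
    for theta in angles:
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, s], [-s, c]])  # rotate by -theta
        proj = hull @ rot.T
        lo, hi = proj.min(axis=0), proj.max(axis=0)
        dx, dy = hi - lo
        area = dx * dy
        if dx >= dy:
            length, width = dx, dy
            orient = np.degrees(theta) % 180.0
        else:
            length, width = dy, dx
            orient = np.degrees(theta + np.pi / 2.0) % 180.0
        mid = (lo + hi) / 2.0
        center = rot.T @ mid
        cand = (area, orient, length, width, center)
        if (
            best is None
            or area < best[0] - 1e-12 * best[0]
            or (abs(area - best[0]) <= 1e-12 * best[0] and orient < best[1])
        ):
            best = cand
    assert best is not None
    area, orient, length, width, center = best
    if width <= 1e-12 * max(length, 1.0):
        raise ValueError("degenerate outline (zero width)")
    return float(length), float(width), float(orient), center


def cell_lwr(outline: CellOutline | np.ndarray) -> float:
    """Length-to-width ratio of the cell's minimal bounding rectangle (>= 1)."""
    v = outline.vertices if isinstance(outline, CellOutline) else outline
    length, width, _, _ = min_bounding_rectangle(v)
    return float(length / width)


def cell_metrics(outline: CellOutline) -> CellMetrics:
    length, width, orient, _ = min_bounding_rectangle(outline.vertices)
    return CellMetrics(
        cell_id=outline.id,
        area=cell_area(outline),
        lwr=float(length / width),
        mbr_length=length,
        mbr_width=width,
        mbr_orientation=orient,
    )


def _ring_moments(ring: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed area, first and second raw moments of a closed coordinate ring."""
    x, y = ring[:-1, 0], ring[:-1, 1]
    x1, y1 = ring[1:, 0], ring[1:, 1]
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    sx = np.sum(cross * (x + x1)) / 6.0
    sy = np.sum(cross * (y + y1)) / 6.0
    sxx = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0
    syy = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0
    sxy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    return a, sx, sy, sxx, syy, sxy


def _region_principal_axis(region: Polygon | MultiPolygon) -> float:
    """Principal (major) axis angle of a region's area moments, deg in [0,180)."""
    polys = region.geoms if isinstance(region, MultiPolygon) else [region]
    a = sx = sy = sxx = syy = sxy = 0.0
    for p in polys:
        rings = [np.asarray(p.exterior.coords)]
        rings += [np.asarray(r.coords) for r in p.interiors]
        for i, ring in enumerate(rings):
            m = np.array(_ring_moments(ring))
            if m[0] < 0:  # normalise ring winding so its own area is positive
                m = -m
            if i > 0:  # holes subtract
                m = -m
            a += m[0]
            sx += m[1]
            sy += m[2]
            sxx += m[3]
            syy += m[4]
            sxy += m[5]
    if a <= 0:
        raise ValueError("empty region")
    cx, cy = sx / a, sy / a
    # central second moments
    mxx = sxx - a * cx * cx
    myy = syy - a * cy * cy
    mxy = sxy - a * cx * cy
    # major axis of the covariance-like tensor [[mxx, mxy], [mxy, myy]]
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    return float(np.degrees(theta) % 180.0)


def blade_metrics(snapshot: EmbryoSnapshot) -> BladeMetrics:
    """Blade-level measurements of one snapshot.

    Blade area is literally the sum of living cells' polygon areas. Axes come
    from the principal area moments of the union of living cells (overlaps do
    not double count in the moments); length and width are the union's extents
    projected on the main and secondary axes. Ablated and excluded cells are
    ignored throughout.
    """
    alive = [c for c in snapshot.cells if c.status is CellStatus.ALIVE]
    if not alive:
        raise ValueError(f"day {snapshot.day}: no alive cells")
    total = sum(cell_area(c) for c in alive)
    union = unary_union([Polygon(c.vertices) for c in alive])
    if union.is_empty:
        raise ValueError(f"day {snapshot.day}: empty union")
    theta_deg = _region_principal_axis(union)
    theta = np.radians(theta_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    v = np.array([-np.sin(theta), np.cos(theta)])
    pts = np.vstack([np.asarray(c.vertices) for c in alive])
    proj_u = pts @ u
    proj_v = pts @ v
    length = float(np.ptp(proj_u))
    width = float(np.ptp(proj_v))
    orient = theta_deg
    if width > length:  # principal axis should be the long one; swap if not
        length, width = width, length
        orient = (theta_deg + 90.0) % 180.0
    if width <= 0:
        raise ValueError("degenerate blade (zero width)")
    return BladeMetrics(
        day=snapshot.day,
        blade_area=float(total),
        length=length,
        width=width,
        lwr=length / width,
        main_axis_orientation=orient,
        n_cells_alive=len(alive),
    )
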