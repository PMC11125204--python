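"""Geometry operations against independent oracles and invariances."""

import numpy as np
import pytest
import shapely
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon

from kelpmorph.core import CellOutline, CellStatus, EmbryoSnapshot
from kelpmorph.morphometry import (
    blade_metrics,
    cell_lwr,
    cell_metrics,
    convex_hull,
    min_bounding_rectangle,
    polygon_area,
)


def star_polygon(rng, n=20, r_lo=1.0, r_hi=5.0):
    """Random star-shaped simple polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(r_lo, r_hi, n)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def _cross(o, a, b):
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def ear_clip_area(vertices):
    """Triangulation oracle: ear clipping, summing triangle areas.

    Independent of the shoelace formula; works for any simple polygon.
    """
    poly = [tuple(p) for p in np.asarray(vertices, float)]
    # orient CCW using the leftmost-lowest vertex turn, not the shoelace sum
    pivot = min(range(len(poly)), key=lambda i: poly[i])
    prev, nxt = poly[pivot - 1], poly[(pivot + 1) % len(poly)]
    if _cross(prev, poly[pivot], nxt) < 0:
        poly.reverse()

    def point_in_tri(p, a, b, c):
        d1, d2, d3 = _cross(a, b, p), _cross(b, c, p), _cross(c, a, p)
        return d1 >= 0 and d2 >= 0 and d3 >= 0

    total = 0.0
    guard = 10 * len(poly) ** 2
    while len(poly) > 3 and guard > 0:
        guard -= 1
        n = len(poly)
        for i in range(n):
            a, b, c = poly[i - 1], poly[i], poly[(i + 1) % n]
            if _cross(a, b, c) <= 0:
                continue  # reflex or collinear: not an ear
            others = [p for j, p in enumerate(poly) if j not in (i - 1, i, (i + 1) % n)]
            if any(point_in_tri(p, a, b, c) for p in others):
                continue
            total += 0.5 * abs(_cross(a, b, c))
            del poly[i]
            break
    a, b, c = poly
    return total + 0.5 * abs(_cross(a, b, c))




def rotate(vertices, deg, about=(0.0, 0.0)):
    th = np.radians(deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (np.asarray(vertices) - about) @ rot.T + about


class TestPolygonArea:
    @pytest.mark.parametrize(
        "verts, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
        ],
    )
    def test_known_shapes(self, verts, expected):
        assert polygon_area(np.array(verts, float)) == pytest.approx(expected)
        # winding independence
        assert polygon_area(np.array(verts, float)[::-1]) == pytest.approx(expected)

    def test_matches_triangulation_oracle(self, rng):
        for _ in range(50):
            poly = star_polygon(rng)
            assert polygon_area(poly) == pytest.approx(ear_clip_area(poly), rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            polygon_area(np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]))


class TestConvexHull:
    def test_square_plus_centroid(self):
        pts = np.array([(0, 0), (2, 0), (2, 2), (0, 2), (1, 1)], float)
        hull = convex_hull(pts)
        assert len(hull) == 4
        assert {tuple(p) for p in hull} == {(0, 0), (2, 0), (2, 2), (0, 2)}

    def test_circle_points_all_retained(self):
        th = np.linspace(0, 2 * np.pi, 17)[:-1]
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert len(convex_hull(pts)) == len(pts)

    def test_containment_and_extremality(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(50, 2))
            hull = convex_hull(pts)
            closed = np.vstack([hull, hull[:1]])
            # every input point on the inner side of every CCW edge
            for p, q in zip(closed, closed[1:]):
                edge, d = q - p, pts - p
                assert (edge[0] * d[:, 1] - edge[1] * d[:, 0] >= -1e-9).all()
            # each hull vertex is the farthest point along its outward normal
            for i, v in enumerate(hull):
                nxt = hull[(i + 1) % len(hull)]
                normal = np.array([nxt[1] - v[1], -(nxt[0] - v[0])])
                proj = pts @ normal
                assert proj.max() <= v @ normal + 1e-9

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            convex_hull(np.array([(0, 0), (1, 1), (2, 2), (3, 3)], float))


class TestMinBoundingRectangle:
    def test_axis_aligned_rectangle(self):
        rect = np.array([(0, 0), (10, 0), (10, 2), (0, 2)], float)
        length, width, orient, _ = min_bounding_rectangle(rect)
        assert (length, width) == pytest.approx((10, 2))
        assert orient == pytest.approx(0.0)

    def test_rotated_rectangle_recovers_orientation(self):
        rect = rotate(np.array([(0, 0), (10, 0), (10, 2), (0, 2)], float), 30)
        length, width, orient, _ = min_bounding_rectangle(rect)
        assert (length, width) == pytest.approx((10, 2))
        assert orient == pytest.approx(30.0)

    def test_beats_angle_sweep_oracle(self, rng):
        # brute-force sweep is an upper bound on the minimum area; the
        # edge-aligned search must not exceed it
        thetas = np.radians(np.arange(0.0, 90.0, 0.01))
        cos, sin = np.cos(thetas), np.sin(thetas)
        for _ in range(25):
            hull = convex_hull(rng.normal(size=(12, 2)) * 3.0)
            x, y = hull[:, 0], hull[:, 1]
            u = np.outer(cos, x) + np.outer(sin, y)
            v = -np.outer(sin, x) + np.outer(cos, y)
            sweep = ((u.max(1) - u.min(1)) * (v.max(1) - v.min(1))).min()
            length, width, _, _ = min_bounding_rectangle(hull)
            assert length * width <= sweep + 1e-6 * sweep

    def test_matches_shapely_oracle(self, rng):
        for _ in range(25):
            hull = convex_hull(rng.normal(size=(15, 2)))
            length, width, _, _ = min_bounding_rectangle(hull)
            oracle = shapely.minimum_rotated_rectangle(Polygon(hull)).area
            assert length * width == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            min_bounding_rectangle(
                np.array([(0, 0), (1, 0), (2, 0), (1, 1e-15)], float)
            )


class TestCellLwr:
    @pytest.mark.parametrize(
        "verts, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (10, 0), (10, 2), (0, 2)], 5.0),
        ],
    )
    def test_known_ratios(self, verts, expected):
        assert cell_lwr(np.array(verts, float)) == pytest.approx(expected)

    @given(
        deg=st.floats(0, 180),
        dx=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    def test_similarity_invariance(self, deg, dx, scale):
        base = np.array([(0, 0), (7, 0), (7, 3), (0, 3)], float)
        moved = rotate(base * scale, deg) + np.array([dx, 1.5 * dx])
        assert cell_lwr(moved) == pytest.approx(cell_lwr(base), rel=1e-9)


def _snapshot_of_rects(rects):
    cells = [
        CellOutline(f"c{i}", np.array(r, float)) for i, r in enumerate(rects)
    ]
    return EmbryoSnapshot(day=0, cells=cells)


class TestBladeMetrics:
    def test_single_rectangle_cell(self):
        snap = _snapshot_of_rects([[(0, 0), (10, 0), (10, 30), (0, 30)]])
        bm = blade_metrics(snap)
        assert bm.blade_area == pytest.approx(300)
        assert bm.length == pytest.approx(30)
        assert bm.width == pytest.approx(10)
        assert bm.lwr == pytest.approx(3)

    def test_stack_of_unit_squares(self):
        rects = [
            [(0, i), (1, i), (1, i + 1), (0, i + 1)] for i in range(4)
        ]
        bm = blade_metrics(_snapshot_of_rects(rects))
        assert bm.blade_area == pytest.approx(4)
        assert bm.length == pytest.approx(4)
        assert bm.width == pytest.approx(1)
        assert bm.lwr == pytest.approx(4)
        assert bm.n_cells_alive == 4

    def test_blade_area_is_sum_of_alive_cell_areas(self, rng):
        rects = [
            [(0, 2 * i), (3, 2 * i), (3, 2 * i + 2), (0, 2 * i + 2)]
            for i in range(5)
        ]
        snap = _snapshot_of_rects(rects)
        snap.cells[0].status = CellStatus.ABLATED
        snap.cells[1].status = CellStatus.EXCLUDED
        bm = blade_metrics(snap)
        expected = sum(polygon_area(c.vertices) for c in snap.cells if c.alive)
        assert bm.blade_area == expected
        assert bm.n_cells_alive == 3

    def test_rigid_invariance(self):
        rects = [
            [(0, 0), (2, 0), (2, 5), (0, 5)],
            [(0, 5), (2, 5), (2, 9), (0, 9)],
        ]
        base = blade_metrics(_snapshot_of_rects(rects))
        moved = _snapshot_of_rects([rotate(np.array(r, float), 77) + 11 for r in rects])
        bm = blade_metrics(moved)
        assert bm.blade_area == pytest.approx(base.blade_area, rel=1e-9)
        assert bm.length == pytest.approx(base.length, rel=1e-9)
        assert bm.width == pytest.approx(base.width, rel=1e-9)

    def test_no_alive_cells_raises(self):
        snap = _snapshot_of_rects([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        snap.cells[0].status = CellStatus.ABLATED
        with pytest.raises(ValueError):
            blade_metrics(snap)


class TestMetricOrdering:
    def test_mbr_bounds_hull_bounds_polygon(self, rng):
        for _ in range(20):
            poly = star_polygon(rng, n=14)
            cm = cell_metrics(CellOutline("c", poly))
            hull_area = polygon_area(convex_hull(poly))
            assert cm.area <= hull_area + 1e-9
            assert hull_area <= cm.mbr_length * cm.mbr_width + 1e-9
            assert cm.lwr >= 1.0
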