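"""Cell tracking across daily snapshots and division-orientation analysis.

Cells are matched between consecutive days by greedy maximal-overlap
assignment on pairwise intersection-over-union (IoU) of their polygons, after
a global translation aligning the two snapshots' living-area centroids. A
parent matched to two children is a division event; the new wall is the
daughters' shared boundary chord, and its acute angle to the blade main axis
classifies the division: parallel (< 45°) = longitudinal, otherwise
transverse. Anomalies (unmatched cells, one-to-many beyond two) are reported,
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from shapely.geometry import Point, Polygon

from .core import CellOutline, CellStatus, EmbryoSnapshot, EmbryoTimeSeries
from .morphometry import blade_metrics

#: Default matching thresholds (tuned on simulated fixtures). Under the
#: order-preserving assignment the IoU floor only rejects gross outliers,
#: so it sits low; raise it for data with erratic per-day drift.
DEFAULT_IOU_THRESHOLD = 0.1
DEFAULT_PAIR_COVERAGE = 0.6
WALL_ADJACENCY_TOL = 0.5  # µm: max daughter-boundary gap when locating a wall


@dataclass(frozen=True)
class DivisionEvent:
    day_before: int
    day_after: int
    parent_id: str
    daughter_ids: tuple[str, str]
    wall: tuple[tuple[float, float], tuple[float, float]]
    orientation: Literal["transverse", "longitudinal"]
    cells_before: int

    @property
    def wall_angle_deg(self) -> float:
        (x0, y0), (x1, y1) = self.wall
        return float(np.degrees(np.arctan2(y1 - y0, x1 - x0)) % 180.0)


@dataclass(frozen=True)
class Anomaly:
    day_before: int
    day_after: int
    code: str  # "unmatched_child" | "one_to_many" | "disjoint_daughters" | ...
    detail: str


@dataclass
class LineageMap:
    day_before: int
    day_after: int
    continuations: dict[str, str] = field(default_factory=dict)  # parent -> child
    divisions: list[DivisionEvent] = field(default_factory=list)
    anomalies: list[Anomaly] = field(default_factory=list)


def _mass_coordinate_transform(cells: list[CellOutline], weighting: str = "area"):
    """Build a map from µm coordinates to (CDF, relative-width) coordinates
    in the cell set's principal-axis frame.

    Each cell's weight is spread uniformly over its main-axis span, giving a
    piecewise-linear monotone CDF. ``weighting='area'`` uses polygon areas
    (divisions conserve area, so daughters tile the parent's slot exactly);
    ``weighting='count'`` gives every cell one unit (a rank CDF, insensitive
    to differential growth and to the shrunken geometry of ablation
    remnants). The two are complementary: matching scores use the better of
    the two.
    """
    pts = np.vstack([c.vertices for c in cells])
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T) if len(pts) > 2 else np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    u_dir = evecs[:, int(np.argmax(evals))]
    # fix the axis sign deterministically (largest |component| positive)
    if u_dir[int(np.argmax(np.abs(u_dir)))] < 0:
        u_dir = -u_dir
    v_dir = np.array([-u_dir[1], u_dir[0]])

    if weighting == "count":
        weights = np.ones(len(cells))
    else:
        weights = np.array([Polygon(c.vertices).area for c in cells])
    spans = np.array(
        [(np.min(c.vertices @ u_dir), np.max(c.vertices @ u_dir)) for c in cells]
    )
    total = weights.sum()
    v_all = pts @ v_dir
    v_mid = (v_all.min() + v_all.max()) / 2.0
    v_width = max(v_all.max() - v_all.min(), 1e-12)

    def xform(verts: np.ndarray) -> np.ndarray:
        verts = np.asarray(verts, float)
        u = verts @ u_dir
        frac = np.clip(
            (u[:, None] - spans[:, 0]) / np.maximum(spans[:, 1] - spans[:, 0], 1e-12),
            0.0,
            1.0,
        )
        cdf = (frac * weights).sum(axis=1) / total
        v = (verts @ v_dir - v_mid) / v_width
        return np.column_stack([cdf, v])

    return xform


def _iou(p: Polygon, q: Polygon) -> float:
    inter = p.intersection(q).area
    if inter == 0.0:
        return 0.0
    return inter / (p.area + q.area - inter)


def _sort_key(poly: Polygon) -> tuple[float, float]:
    c = poly.centroid
    return (round(c.x, 6), round(c.y, 6))  # mass coords: (axis CDF, width)


def _order_preserving_assignment(
    score: np.ndarray, threshold: float
) -> dict[int, list[int]]:
    """Best stack-order-preserving parent→children assignment.

    ``score[i, j]`` is the overlap of parent ``i`` with child ``j``, both in
    stack order. Each parent takes 0, 1 or 2 consecutive children; skipped
    children stay unmatched. Maximises total overlap (small penalties make
    skipping strictly worse than any admissible match).
    """
    m, n = score.shape
    NEG = -np.inf
    # cells neither appear from nowhere nor vanish (ablation keeps the
    # remnant visible), so leaving a cell unmatched must cost more than the
    # marginal gain of a drifting neighbour grabbing it as a second child
    skip_pen = 0.3
    dp = np.full((m + 1, n + 1), NEG)
    dp[0, 0] = 0.0
    back: dict[tuple[int, int], tuple[int, int, str]] = {}

    def relax(i2: int, j2: int, val: float, src: tuple[int, int], how: str) -> None:
        if val > dp[i2, j2]:
            dp[i2, j2] = val
            back[(i2, j2)] = (*src, how)

    for i in range(m + 1):
        for j in range(n + 1):
            cur = dp[i, j]
            if cur == NEG:
                continue
            if i < m:
                relax(i + 1, j, cur - skip_pen, (i, j), "skip_parent")
            if j < n:
                relax(i, j + 1, cur - skip_pen, (i, j), "skip_child")
            if i < m and j < n and score[i, j] >= threshold:
                relax(i + 1, j + 1, cur + score[i, j], (i, j), "one")
                if j + 1 < n and score[i, j + 1] >= threshold:
                    relax(
                        i + 1,
                        j + 2,
                        cur + score[i, j] + score[i, j + 1],
                        (i, j),
                        "two",
                    )
    out: dict[int, list[int]] = {}
    i, j = m, n
    while (i, j) != (0, 0):
        pi, pj, how = back[(i, j)]
        if how == "one":
            out[pi] = [pj]
        elif how == "two":
            out[pi] = [pj, pj + 1]
        i, j = pi, pj
    return out


def division_wall(
    daughter_a: CellOutline,
    daughter_b: CellOutline,
    tol: float = WALL_ADJACENCY_TOL,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the shared boundary chord between two daughter cells.

    The chord spans the longest run of boundary points of one daughter lying
    within ``tol`` of the other's boundary. Raises ``ValueError`` when the
    daughters are not adjacent.
    """
    pa, pb = Polygon(daughter_a.vertices), Polygon(daughter_b.vertices)
    shared = pa.exterior.intersection(pb.exterior)
    pts: list[np.ndarray] = []
    if not shared.is_empty:
        geoms = getattr(shared, "geoms", [shared])
        for g in geoms:
            pts.extend(np.asarray(g.coords))
    # jittered outlines rarely intersect exactly: fall back to near-contact
    # vertices of either boundary
    if len(pts) < 2:
        for verts, other in ((daughter_a.vertices, pb), (daughter_b.vertices, pa)):
            for v in verts:
                if other.exterior.distance(Point(v)) <= tol:
                    pts.append(np.asarray(v, float))
    if len(pts) < 2:
        raise ValueError(
            f"daughters {daughter_a.id!r}/{daughter_b.id!r} are not adjacent"
        )
    arr = np.asarray(pts, float)
    # chord = most separated pair (O(n²) fine: outlines are small)
    d2 = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i, j] <= 0:
        raise ValueError("zero-length division wall")
    return (tuple(arr[i]), tuple(arr[j]))


def _bisector_wall(
    daughter_a: CellOutline, daughter_b: CellOutline
) -> tuple[tuple[float, float], tuple[float, float]]:
    ca = np.asarray(Polygon(daughter_a.vertices).centroid.coords[0])
    cb = np.asarray(Polygon(daughter_b.vertices).centroid.coords[0])
    axis = cb - ca
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("coincident daughter centroids")
    d = np.array([-axis[1], axis[0]]) / norm
    mid = (ca + cb) / 2.0
    half = norm / 2.0
    return (tuple(mid - d * half), tuple(mid + d * half))


def classify_division(
    wall: tuple[tuple[float, float], tuple[float, float]],
    blade_main_axis_deg: float,
) -> Literal["transverse", "longitudinal"]:
    """Orientation class of a new wall relative to the embryo growth axis.

    A longitudinal division has its wall parallel to the growth (main) axis;
    the acute wall-to-axis angle φ < 45° maps to longitudinal, φ >= 45°
    (including the tie) to transverse — early embryos divide transversally by
    default, so the tie preserves the default class.
    """
    (x0, y0), (x1, y1) = wall
    if x0 == x1 and y0 == y1:
        raise ValueError("zero-length division wall")
    wall_deg = np.degrees(np.arctan2(y1 - y0, x1 - x0)) % 180.0
    phi = abs(wall_deg - blade_main_axis_deg) % 180.0
    phi = min(phi, 180.0 - phi)
    return "longitudinal" if phi < 45.0 else "transverse"


def match_lineage(
    snapshot_t: EmbryoSnapshot,
    snapshot_t1: EmbryoSnapshot,
    *,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    pair_coverage: float = DEFAULT_PAIR_COVERAGE,
    align: bool = True,
    basal_end: str = "min_axis",
    cells_at_t: Optional[int] = None,
) -> LineageMap:
    """Match cells of two consecutive snapshots and detect divisions.

    Greedy assignment: child→parent pairs are taken in decreasing IoU order;
    each child gets one parent, a parent at most two children. Two children
    whose polygons jointly cover at least ``pair_coverage`` of the parent
    area form a :class:`DivisionEvent`. ``cells_before`` of simultaneous
    events (same day pair) follows the apical-most-parent-first order along
    the blade main axis, mirroring observed asynchronous division order.
    """
    if not snapshot_t.cells or not snapshot_t1.cells:
        raise ValueError("cannot match against an empty snapshot")
    # ablation remnants take part in matching (a daughter may be ablated at
    # its first appearance) but never in living counts
    parents = [c for c in snapshot_t.cells if c.status is not CellStatus.EXCLUDED]
    children = [c for c in snapshot_t1.cells if c.status is not CellStatus.EXCLUDED]
    n_living_parents = sum(c.alive for c in parents)
    if align:
        # Blades elongate several-fold between snapshots and the apical
        # region grows faster than the basal one, so neither a rigid shift
        # nor a global scaling keeps a cell over its own slot. Instead both
        # snapshots are mapped to mass coordinates: along the blade main
        # axis, a point's coordinate becomes the fraction of total cell
        # area basal to it (area CDF); across the axis, position is
        # normalised by the local blade width. Divisions conserve area, so
        # a parent's area-share interval contains its daughters' almost
        # exactly, and day-to-day drift is only the differential-growth
        # share change.
        transforms = [
            (
                _mass_coordinate_transform(parents, w),
                _mass_coordinate_transform(children, w),
            )
            for w in ("area", "count")
        ]
    else:
        ident = lambda v: np.asarray(v, float)  # noqa: E731
        transforms = [(ident, ident)]

    poly_pairs = [
        (
            {c.id: Polygon(xp(c.vertices)) for c in parents},
            {c.id: Polygon(xc(c.vertices)) for c in children},
        )
        for xp, xc in transforms
    ]
    ppolys, cpolys = poly_pairs[0]
    # Cells never pass one another along the growth axis, so lineage is
    # order preserving: in stack order each parent continues as one child or
    # divides into two consecutive children. The maximal-overlap assignment
    # under that constraint is found by dynamic programming, which keeps a
    # drifting continuation from stealing a neighbour's daughter.
    parents_sorted = sorted(
        parents, key=lambda c: _sort_key(ppolys[c.id])
    )
    children_sorted = sorted(
        children, key=lambda c: _sort_key(cpolys[c.id])
    )
    score = np.max(
        [
            [
                [_iou(pp[p.id], cp[ch.id]) for ch in children_sorted]
                for p in parents_sorted
            ]
            for pp, cp in poly_pairs
        ],
        axis=0,
    )
    assign = _order_preserving_assignment(score, iou_threshold)
    child_parent: dict[str, str] = {}
    parent_children: dict[str, list[str]] = {p.id: [] for p in parents}
    for pi, kids_idx in assign.items():
        pid = parents_sorted[pi].id
        for cj in kids_idx:
            cid = children_sorted[cj].id
            child_parent[cid] = pid
            parent_children[pid].append(cid)

    lm = LineageMap(day_before=snapshot_t.day, day_after=snapshot_t1.day)
    for ch in children:
        if ch.id not in child_parent:
            lm.anomalies.append(
                Anomaly(snapshot_t.day, snapshot_t1.day, "unmatched_child",
                        f"cell {ch.id!r} has no parent")
            )

    axis = blade_metrics(snapshot_t).main_axis_orientation
    theta_ax = np.radians(axis)
    u = np.array([np.cos(theta_ax), np.sin(theta_ax)])
    w = np.array([-np.sin(theta_ax), np.cos(theta_ax)])  # secondary axis
    sign = 1.0 if basal_end == "min_axis" else -1.0

    raw_events = []
    for pid, kids in parent_children.items():
        if len(kids) == 1:
            lm.continuations[pid] = kids[0]
        elif len(kids) == 2 and not snapshot_t[pid].alive:
            lm.anomalies.append(
                Anomaly(snapshot_t.day, snapshot_t1.day, "remnant_division",
                        f"remnant {pid!r} matched two children {kids}")
            )
        elif len(kids) == 2:
            cov = max(
                sum(pp[pid].intersection(cp[k]).area for k in kids)
                / pp[pid].area
                for pp, cp in poly_pairs
            )
            if cov < pair_coverage:
                lm.anomalies.append(
                    Anomaly(snapshot_t.day, snapshot_t1.day, "low_coverage",
                            f"parent {pid!r} children cover {cov:.2f} of its area")
                )
                continue
            da = snapshot_t1[kids[0]]
            db = snapshot_t1[kids[1]]
            try:
                wall = division_wall(da, db)
            except ValueError as exc:
                if da.alive and db.alive:
                    lm.anomalies.append(
                        Anomaly(snapshot_t.day, snapshot_t1.day,
                                "disjoint_daughters", str(exc))
                    )
                    continue
                # a shrunken remnant daughter is no longer adjacent to its
                # sister: infer the wall as the perpendicular bisector of
                # the daughters' centroid segment
                wall = _bisector_wall(da, db)
            orientation = classify_division(wall, axis)
            # apical position of the parent along the main axis (µm frame);
            # ties (side-by-side parents dividing the same day) broken by
            # secondary-axis position
            centroid = np.asarray(
                Polygon(snapshot_t[pid].vertices).centroid.coords[0]
            )
            apical_pos = sign * float(centroid @ u)
            perp_pos = float(centroid @ w)
            raw_events.append(
                (apical_pos, perp_pos, pid, tuple(sorted(kids)), wall, orientation)
            )

    n_before = n_living_parents if cells_at_t is None else cells_at_t
    for k, (_, _, pid, kids, wall, orientation) in enumerate(
        sorted(raw_events, key=lambda t: (-round(t[0], 6), round(t[1], 6)))
    ):
        lm.divisions.append(
            DivisionEvent(
                day_before=snapshot_t.day,
                day_after=snapshot_t1.day,
                parent_id=pid,
                daughter_ids=kids,
                wall=wall,
                orientation=orientation,
                cells_before=n_before + k,
            )
        )
    return lm


def track_series(series: EmbryoTimeSeries, **kwargs) -> list[LineageMap]:
    """Run :func:`match_lineage` over every consecutive snapshot pair."""
    maps = []
    for a, b in zip(series.snapshots, series.snapshots[1:]):
        maps.append(match_lineage(a, b, basal_end=series.basal_end, **kwargs))
    return maps


def first_longitudinal_stage(
    maps: list[LineageMap],
) -> Optional[int]:
    """Living-cell count immediately before the earliest longitudinal
    division, or ``None`` if no longitudinal division was observed."""
    for lm in maps:
        for ev in lm.divisions:  # already in within-pair processing order
            if ev.orientation == "longitudinal":
                return ev.cells_before
    return None
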