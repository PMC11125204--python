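"""Read and write embryo segmentation documents (Inkscape-style SVG).

Document layout: one ``<g>`` element per daily time point, labelled ``d00``,
``d01``, … (via ``inkscape:label`` or ``id``); inside each group one closed
``<path>`` (or ``<polygon>``) per cell, carrying the cell ``id``. Fill colour
encodes status: a grey fill (``#808080`` by default, palette configurable)
marks a laser-ablation remnant; ``class="excluded"`` marks a cell removed
from the analysis. Coordinates are drawing units; a calibration factor
(µm per unit) converts to µm on read.

Bezier segments are flattened to polylines at a configurable chord tolerance.
Vertex order is normalised counter-clockwise on read, so downstream geometry
is invariant to the winding the editor happened to save.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from shapely.geometry import Polygon

from .core import CellOutline, CellStatus, EmbryoSnapshot, EmbryoTimeSeries

SVG_NS = "http://www.w3.org/2000/svg"
INKSCAPE_NS = "http://www.inkscape.org/namespaces/inkscape"
NSMAP = {"svg": SVG_NS, "inkscape": INKSCAPE_NS}

#: Fill colours interpreted as "ablated remnant" (Fig-2-style grey).
DEFAULT_ABLATED_FILLS = frozenset({"#808080", "#7f7f7f", "grey", "gray"})

_DAY_RE = re.compile(r"^d(\d{2,})$")
_NUM_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


class SegmentationError(ValueError):
    """Raised for malformed segmentation documents."""


# ---------------------------------------------------------------------------
# path-data parsing


def _flatten_cubic(p0, p1, p2, p3, tol: float) -> list[np.ndarray]:
    """Flatten one cubic Bezier to points (excluding p0) within chord
    tolerance ``tol`` by uniform subdivision."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    # control-polygon deviation bounds the curve-chord distance
    dev = max(
        np.linalg.norm(p1 - (2 * p0 + p3) / 3.0),
        np.linalg.norm(p2 - (p0 + 2 * p3) / 3.0),
    )
    n = max(2, int(np.ceil(np.sqrt(max(dev, 1e-12) / max(tol, 1e-9)) * 4)))
    t = np.linspace(0.0, 1.0, n + 1)[1:]
    mt = 1.0 - t
    pts = (
        np.outer(mt**3, p0)
        + np.outer(3 * mt**2 * t, p1)
        + np.outer(3 * mt * t**2, p2)
        + np.outer(t**3, p3)
    )
    return [p for p in pts]


def parse_path_data(d: str, chord_tolerance: float = 0.1) -> np.ndarray:
    """Parse an SVG path ``d`` attribute into a closed polyline's vertices.

    Supports M/m, L/l, H/h, V/v, C/c, Z/z — the commands Inkscape emits for
    hand-drawn outlines. The path must consist of a single closed subpath.
    """
    tokens = re.findall(r"[MmLlHhVvCcZz]|" + _NUM_RE.pattern, d)
    pts: list[np.ndarray] = []
    cur = np.zeros(2)
    closed = False
    i = 0
    cmd = None
    n_sub = 0

    def take(k: int) -> list[float]:
        nonlocal i
        vals = [float(t) for t in tokens[i : i + k]]
        if len(vals) < k:
            raise SegmentationError(f"truncated path data: {d!r}")
        i += k
        return vals

    while i < len(tokens):
        t = tokens[i]
        if t in "MmLlHhVvCcZz":
            cmd = t
            i += 1
            if cmd in "Zz":
                closed = True
                continue
        elif cmd is None:
            raise SegmentationError(f"path data must start with a command: {d!r}")
        if closed and cmd not in "Zz":
            raise SegmentationError("multiple subpaths are not supported")
        if cmd in "Mm":
            x, y = take(2)
            cur = np.array([x, y]) + (cur if cmd == "m" and pts else 0.0)
            if pts:
                raise SegmentationError("multiple subpaths are not supported")
            pts.append(cur.copy())
            n_sub += 1
            cmd = "L" if cmd == "M" else "l"  # implicit lineto after moveto
        elif cmd in "Ll":
            x, y = take(2)
            cur = np.array([x, y]) + (cur if cmd == "l" else 0.0)
            pts.append(cur.copy())
        elif cmd in "Hh":
            (x,) = take(1)
            cur = np.array([x + (cur[0] if cmd == "h" else 0.0), cur[1]])
            pts.append(cur.copy())
        elif cmd in "Vv":
            (y,) = take(1)
            cur = np.array([cur[0], y + (cur[1] if cmd == "v" else 0.0)])
            pts.append(cur.copy())
        elif cmd in "Cc":
            vals = take(6)
            rel = cur if cmd == "c" else np.zeros(2)
            c1 = np.array(vals[0:2]) + rel
            c2 = np.array(vals[2:4]) + rel
            end = np.array(vals[4:6]) + rel
            pts.extend(_flatten_cubic(cur, c1, c2, end, chord_tolerance))
            cur = end
        else:  # pragma: no cover - guarded by the token regex
            raise SegmentationError(f"unsupported path command {cmd!r}")
    if not closed:
        raise SegmentationError(f"open path (no Z): {d!r}")
    v = np.asarray(pts, float)
    if len(v) >= 2 and np.allclose(v[0], v[-1], atol=1e-12):
        v = v[:-1]
    return v


# ---------------------------------------------------------------------------
# geometry validation helpers


def _normalize_ccw(vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return vertices[::-1].copy() if signed < 0 else vertices


def is_simple_polygon(vertices: np.ndarray) -> bool:
    if len(vertices) < 3:
        return False
    return Polygon(vertices).is_valid


# ---------------------------------------------------------------------------
# reading


def _group_day(g) -> int | None:
    label = g.get(f"{{{INKSCAPE_NS}}}label") or g.get("id") or ""
    m = _DAY_RE.match(label)
    return int(m.group(1)) if m else None


def _style_fill(el) -> str | None:
    fill = el.get("fill")
    style = el.get("style") or ""
    for part in style.split(";"):
        k, _, val = part.partition(":")
        if k.strip() == "fill":
            fill = val.strip()
    return fill.lower() if fill else None


def _element_outline(
    el,
    calibration: float,
    chord_tolerance: float,
    ablated_fills: frozenset[str],
) -> CellOutline:
    tag = etree.QName(el).localname
    cid = el.get("id")
    if not cid:
        raise SegmentationError(f"<{tag}> without id attribute")
    if tag == "path":
        verts = parse_path_data(el.get("d") or "", chord_tolerance)
    elif tag == "polygon":
        nums = [float(x) for x in _NUM_RE.findall(el.get("points") or "")]
        verts = np.asarray(nums, float).reshape(-1, 2)
    else:
        raise SegmentationError(f"cell {cid!r}: unsupported element <{tag}>")
    verts = verts * calibration
    if len(verts) < 3:
        raise SegmentationError(f"cell {cid!r}: fewer than 3 vertices")
    if not is_simple_polygon(verts):
        raise SegmentationError(f"cell {cid!r}: self-intersecting outline")
    status = CellStatus.ALIVE
    if "excluded" in (el.get("class") or "").split():
        status = CellStatus.EXCLUDED
    elif (_style_fill(el) or "") in ablated_fills:
        status = CellStatus.ABLATED
    return CellOutline(cid, _normalize_ccw(verts), status)


def read_segmentation(
    source,
    calibration: float,
    condition: str,
    embryo_id: str,
    *,
    chord_tolerance: float = 0.1,
    ablated_fills: frozenset[str] = DEFAULT_ABLATED_FILLS,
) -> EmbryoTimeSeries:
    """Parse a segmentation SVG into an :class:`EmbryoTimeSeries`.

    ``source`` is a path, file object, or bytes. ``calibration`` is µm per
    drawing unit. Raises :class:`SegmentationError` with the offending cell
    id for malformed outlines.
    """
    if calibration <= 0:
        raise SegmentationError("calibration must be > 0")
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:  # path-like or file object
        root = etree.parse(str(source) if hasattr(source, "__fspath__")
                           else source).getroot()

    basal_end = root.get("basal_end") or "min_axis"
    snapshots = []
    groups = root.findall(f"{{{SVG_NS}}}g")
    if not groups:
        raise SegmentationError("document contains no snapshot groups")
    day_groups = []
    for g in groups:
        day = _group_day(g)
        if day is None:
            raise SegmentationError(
                f"group {g.get('id')!r} has no dNN label"
            )
        day_groups.append((day, g))
    for day, g in sorted(day_groups):
        cells = []
        for el in g:
            if etree.QName(el).localname in ("path", "polygon"):
                cells.append(
                    _element_outline(el, calibration, chord_tolerance, ablated_fills)
                )
        if not cells:
            raise SegmentationError(f"snapshot d{day:02d} is empty")
        snapshots.append(EmbryoSnapshot(day=day, cells=cells))
    return EmbryoTimeSeries(
        embryo_id=embryo_id,
        condition=condition,
        snapshots=snapshots,
        calibration=calibration,
        basal_end=basal_end,
    )


# ---------------------------------------------------------------------------
# writing


def write_segmentation(series: EmbryoTimeSeries, path=None) -> bytes:
    """Serialise a series to SVG (inverse of :func:`read_segmentation`).

    Coordinates are written in drawing units (µm / calibration) at full float
    precision; cells are ordered by day then id; remnants get the grey fill,
    excluded cells the ``excluded`` class. Returns the document bytes and, if
    ``path`` is given, also writes them there.
    """
    if not series.snapshots:
        raise SegmentationError("cannot write an empty series")
    root = etree.Element(
        f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS, "inkscape": INKSCAPE_NS}
    )
    root.set("basal_end", series.basal_end)
    root.set("data-embryo-id", series.embryo_id)
    root.set("data-condition", series.condition)
    for snap in series.snapshots:
        if not snap.cells:
            raise SegmentationError(f"snapshot day {snap.day} has no cells")
        label = f"d{snap.day:02d}"
        g = etree.SubElement(root, f"{{{SVG_NS}}}g", id=label)
        g.set(f"{{{INKSCAPE_NS}}}label", label)
        for cell in sorted(snap.cells, key=lambda c: c.id):
            pts = cell.vertices / series.calibration
            d = (
                "M "
                + " L ".join(f"{x:.10g},{y:.10g}" for x, y in pts)
                + " Z"
            )
            el = etree.SubElement(g, f"{{{SVG_NS}}}path", id=cell.id)
            el.set("d", d)
            if cell.status is CellStatus.ABLATED:
                el.set("fill", "#808080")
            elif cell.status is CellStatus.EXCLUDED:
                el.set("class", "excluded")
                el.set("fill", "none")
            else:
                el.set("fill", "none")
            el.set("stroke", "#000000")
    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]


def validate_series(series: EmbryoTimeSeries) -> ValidationReport:
    """Itemise geometry and bookkeeping problems; empty report means clean."""
    report = ValidationReport()
    add = report.violations.append
    prev_day = None
    for snap in series.snapshots:
        seen: set[str] = set()
        for cell in snap.cells:
            if cell.id in seen:
                add(Violation("error", "duplicate_id",
                              f"day {snap.day}: duplicate cell id {cell.id!r}"))
            seen.add(cell.id)
            if len(cell.vertices) < 3:
                add(Violation("error", "too_few_vertices",
                              f"day {snap.day}: cell {cell.id!r} has <3 vertices"))
                continue
            if not is_simple_polygon(cell.vertices):
                add(Violation("error", "non_simple",
                              f"day {snap.day}: cell {cell.id!r} is self-intersecting"))
                continue
            if Polygon(cell.vertices).area <= 0:
                add(Violation("error", "zero_area",
                              f"day {snap.day}: cell {cell.id!r} has zero area"))
        if prev_day is not None and snap.day - prev_day > 1:
            add(Violation("warning", "day_gap",
                          f"gap between day {prev_day} and day {snap.day}"))
        prev_day = snap.day
    return report
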