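"""Agent-based simulator of early kelp-embryo growth.

The model: the embryo grows as a stack of cells along one axis. Growth is
cell-autonomous with an apical bias — the per-day fractional elongation is
interpolated linearly from ``growth_rate_basal`` at the basal-most cell to
``growth_rate_apical`` at the apical-most. A cell divides when its area
reaches ``division_area_factor`` times its birth area. Division orientation is
governed by a basal inhibition of finite range: a cell divides longitudinally
(new wall parallel to the growth axis, i.e. it splits its width) only if the
original basal cell's lineage is dead, or the cell lies more than
``inhibition_range_R`` living cells above the base; otherwise it divides
transversally (splits its height). Laser ablation converts one end cell into
an inert remnant which stays visible but never grows or divides.

With growth noise and vertex jitter disabled the run is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .core import CellOutline, CellStatus, EmbryoSnapshot


@dataclass(frozen=True)
class AblationPlan:
    """Ablate the apical- or basal-most living cell when the living-cell
    count first equals ``stage`` at a snapshot."""

    target: Literal["apical", "basal"]
    stage: int

    def __post_init__(self) -> None:
        if self.target not in ("apical", "basal"):
            raise ValueError("ablation target must be 'apical' or 'basal'")
        if self.stage < 2:
            raise ValueError("ablation stage must be >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the basal-inhibition / apical-growth-gradient model.

    Lengths in µm, rates in fractional elongation per day. Defaults are
    calibration choices that reproduce the observed intact onset of
    longitudinal division at the 8-cell stage; they are not measured values.
    """

    initial_length: float = 35.0  # zygote height, µm
    initial_width: float = 10.0  # µm
    growth_rate_basal: float = 0.45  # g_b, per day
    growth_rate_apical: float = 0.9  # g_a, per day
    division_area_factor: float = 2.0
    inhibition_range_R: int = 6  # rank units
    days: int = 9
    snapshot_interval: int = 1
    ablation: Optional[AblationPlan] = None
    remnant_fraction: float = 0.6
    noise_growth_cv: float = 0.0
    vertex_jitter_sd: float = 0.0  # µm; applied at rendering time
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.growth_rate_apical >= self.growth_rate_basal > 0):
            raise ValueError("need g_a >= g_b > 0 (apical growth bias)")
        if self.inhibition_range_R < 0:
            raise ValueError("inhibition_range_R must be >= 0")
        if self.division_area_factor <= 1:
            raise ValueError("division_area_factor must be > 1")
        if min(self.initial_length, self.initial_width) <= 0:
            raise ValueError("initial dimensions must be > 0")
        if not (0 < self.remnant_fraction <= 1):
            raise ValueError("remnant_fraction must be in (0, 1]")
        if self.days < 1 or self.snapshot_interval < 1:
            raise ValueError("days and snapshot_interval must be >= 1")
        if self.noise_growth_cv < 0 or self.vertex_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SimCell:
    id: str
    height: float
    width: float
    x0: float  # left edge, µm
    birth_area: float
    status: CellStatus = CellStatus.ALIVE

    @property
    def area(self) -> float:
        return self.height * self.width


@dataclass(frozen=True)
class DivisionRecord:
    day: int
    parent_id: str
    daughter1_id: str
    daughter2_id: str
    orientation: Literal["transverse", "longitudinal"]
    cells_before: int  # living-cell count immediately before this division


@dataclass
class EmbryoState:
    """Mutable simulator state: tiers of cells, basal tier first.

    Cells in one tier sit side by side (products of longitudinal divisions);
    a pure stack has one cell per tier. ``basal_lineage_alive`` tracks whether
    the original basal cell's basal-most descendant is still alive — the
    source of the longitudinal-division inhibition.
    """

    tiers: list[list[SimCell]]
    basal_lineage_alive: bool = True
    next_id: int = 1

    def living(self) -> list[SimCell]:
        return [c for t in self.tiers for c in t if c.status is CellStatus.ALIVE]

    def n_living(self) -> int:
        return len(self.living())

    def rank_of_tier(self, tier_index: int) -> int:
        """Living cells in strictly more-basal tiers."""
        return sum(
            1
            for t in self.tiers[:tier_index]
            for c in t
            if c.status is CellStatus.ALIVE
        )

    def fresh_id(self) -> str:
        cid = f"c{self.next_id:04d}"
        self.next_id += 1
        return cid


@dataclass(frozen=True)
class SimulatedSeries:
    snapshots: list[EmbryoSnapshot]
    lineage_truth: list[DivisionRecord]
    config: SimulationConfig

    def first_longitudinal_stage(self) -> Optional[int]:
        for rec in self.lineage_truth:
            if rec.orientation == "longitudinal":
                return rec.cells_before
        return None


def _growth_rate(cfg: SimulationConfig, position_fraction: float) -> float:
    """Positional growth gradient: fractional elongation per day at relative
    axis position ``position_fraction`` (0 = basal pole, 1 = apical pole).

    Linear interpolation g_b -> g_a; a cell elongates at the gradient value
    at its span midpoint, so total blade area always grows at the
    partition-independent mean rate (g_b + g_a) / 2 — growth kinetics do not
    change when part of the embryo is removed (cell-autonomous growth).
    """
    g_b, g_a = cfg.growth_rate_basal, cfg.growth_rate_apical
    return g_b + (g_a - g_b) * position_fraction


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _wants_longitudinal(state: EmbryoState, rank: int, cfg: SimulationConfig) -> bool:
    return (not state.basal_lineage_alive) or rank > cfg.inhibition_range_R


def _grow(state: EmbryoState, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    # relative axis position of each living tier (remnants occupy no living
    # axis: the gradient spans the living tissue)
    living_h = [
        max((c.height for c in t if c.status is CellStatus.ALIVE), default=0.0)
        for t in state.tiers
    ]
    total_h = sum(living_h)
    y = 0.0
    for tier, h in zip(state.tiers, living_h):
        mid_frac = (y + h / 2.0) / total_h if total_h > 0 else 0.0
        y += h
        for cell in tier:
            if cell.status is not CellStatus.ALIVE:
                continue
            g = _growth_rate(cfg, mid_frac)
            eps = _lognormal_factor(rng, cfg.noise_growth_cv)
            factor = 1.0 + g * eps
            if not math.isfinite(factor) or factor <= 0:
                raise RuntimeError(f"non-finite growth factor for {cell.id}")
            cell.height *= factor


def _locate(state: EmbryoState, cell_id: str) -> tuple[int, int]:
    for ti, tier in enumerate(state.tiers):
        for ci, cell in enumerate(tier):
            if cell.id == cell_id:
                return ti, ci
    raise KeyError(cell_id)


def _divide(
    state: EmbryoState, cfg: SimulationConfig, day: int
) -> list[DivisionRecord]:
    """One division pass, apical-most tier first; right-most cell first
    within a tier. The processing order is frozen at the start of the day, so
    newborn daughters are never re-checked the same day (their
    area/birth-area ratio restarts at 1 anyway)."""
    order = [
        cell.id
        for tier in reversed(state.tiers)
        for cell in sorted(tier, key=lambda c: -c.x0)
    ]
    records: list[DivisionRecord] = []
    for cid in order:
        ti, ci = _locate(state, cid)
        cell = state.tiers[ti][ci]
        if cell.status is not CellStatus.ALIVE:
            continue
        if cell.area < cfg.division_area_factor * cell.birth_area - 1e-12:
            continue
        rank = state.rank_of_tier(ti)
        n_before = state.n_living()
        longitudinal = _wants_longitudinal(state, rank, cfg)
        d1, d2 = state.fresh_id(), state.fresh_id()
        if longitudinal:
            half = cell.width / 2.0
            left = SimCell(d1, cell.height, half, cell.x0, cell.area / 2.0)
            right = SimCell(d2, cell.height, half, cell.x0 + half, cell.area / 2.0)
            state.tiers[ti][ci : ci + 1] = [left, right]
        else:
            half = cell.height / 2.0
            lower = SimCell(d1, half, cell.width, cell.x0, cell.area / 2.0)
            upper = SimCell(d2, half, cell.width, cell.x0, cell.area / 2.0)
            # splitting a multi-cell tier leaves non-dividing neighbours
            # anchored in the lower of the two new tiers
            others = [c for c in state.tiers[ti] if c.id != cell.id]
            state.tiers[ti] = others + [lower]
            state.tiers.insert(ti + 1, [upper])
        records.append(
            DivisionRecord(
                day=day,
                parent_id=cell.id,
                daughter1_id=d1,
                daughter2_id=d2,
                orientation="longitudinal" if longitudinal else "transverse",
                cells_before=n_before,
            )
        )
    return records


def apply_ablation(state: EmbryoState, target: str) -> SimCell:
    """Convert the apical- or basal-most living cell into an inert remnant.

    The remnant keeps its outline (uniformly shrunk by the remnant fraction at
    snapshot rendering via its stored geometry), stays in place in later
    snapshots, and is excluded from living counts, growth and division.
    Requires at least two living cells.
    """
    living = state.living()
    if len(living) < 2:
        raise ValueError("ablation needs >= 2 living cells")
    order = [
        (ti, c)
        for ti, tier in enumerate(state.tiers)
        for c in sorted(tier, key=lambda c: c.x0)
        if c.status is CellStatus.ALIVE
    ]
    ti, victim = order[-1] if target == "apical" else order[0]
    victim.status = CellStatus.ABLATED
    if target == "basal" and ti == 0:
        state.basal_lineage_alive = False
    return victim


def _shrink_remnants(state: EmbryoState, frac: float, shrunk: set[str]) -> None:
    for tier in state.tiers:
        for cell in tier:
            if cell.status is CellStatus.ABLATED and cell.id not in shrunk:
                cx = cell.x0 + cell.width / 2.0
                cell.height *= frac
                cell.width *= frac
                cell.x0 = cx - cell.width / 2.0
                shrunk.add(cell.id)


def _snapshot(state: EmbryoState, day: int, frac: float) -> EmbryoSnapshot:
    """Lay tiers out bottom-up and emit rectangular outlines (CCW)."""
    cells: list[CellOutline] = []
    y = 0.0
    for tier in state.tiers:
        tier_h = max(c.height / (frac if c.status is CellStatus.ABLATED else 1.0)
                     for c in tier)
        for cell in sorted(tier, key=lambda c: c.x0):
            if cell.status is CellStatus.ABLATED:
                # centre the shrunken remnant in its tier slot
                y0 = y + (tier_h - cell.height) / 2.0
            else:
                y0 = y
            x0, x1 = cell.x0, cell.x0 + cell.width
            y1 = y0 + cell.height
            verts = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
            cells.append(CellOutline(cell.id, verts, cell.status))
        y += tier_h
    return EmbryoSnapshot(day=day, cells=cells)


def simulate_embryo(config: SimulationConfig) -> SimulatedSeries:
    """Run the model for ``config.days`` days, one snapshot per
    ``snapshot_interval`` days (day 0 included).

    Each day: all living cells grow, then cells at or above the division area
    threshold divide (apical-most first). Ablation, if planned, fires at the
    first snapshot whose living-cell count equals the planned stage; it is an
    error if that stage is never reached.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    zygote = SimCell(
        "c0000",
        height=cfg.initial_length,
        width=cfg.initial_width,
        x0=-cfg.initial_width / 2.0,
        birth_area=cfg.initial_length * cfg.initial_width,
    )
    state = EmbryoState(tiers=[[zygote]])
    records: list[DivisionRecord] = []
    snapshots: list[EmbryoSnapshot] = []
    shrunk: set[str] = set()
    ablation_done = cfg.ablation is None

    def maybe_ablate() -> None:
        # ">=" rather than "==": noisy growth can desynchronise divisions so
        # the living count jumps past the planned stage within one day
        nonlocal ablation_done
        if not ablation_done and state.n_living() >= cfg.ablation.stage:
            apply_ablation(state, cfg.ablation.target)
            _shrink_remnants(state, cfg.remnant_fraction, shrunk)
            ablation_done = True

    maybe_ablate()
    snapshots.append(_snapshot(state, 0, cfg.remnant_fraction))
    for day in range(1, cfg.days + 1):
        _grow(state, cfg, rng)
        records.extend(_divide(state, cfg, day))
        if day % cfg.snapshot_interval == 0:
            maybe_ablate()
            snapshots.append(_snapshot(state, day, cfg.remnant_fraction))
    if not ablation_done:
        raise RuntimeError(
            f"ablation stage {cfg.ablation.stage} never reached within "
            f"{cfg.days} days (final living count {state.n_living()})"
        )
    return SimulatedSeries(snapshots=snapshots, lineage_truth=records, config=cfg)


def to_time_series(
    series: SimulatedSeries,
    embryo_id: str,
    condition: str,
    calibration: float = 1.0,
) -> "EmbryoTimeSeries":
    """Package the simulated snapshots as an :class:`EmbryoTimeSeries`,
    applying vertex jitter (sd = ``config.vertex_jitter_sd`` µm) to emulate
    hand-segmentation error. Jitter preserves simple-polygon validity: a
    jittered outline that self-intersects is re-drawn with halved amplitude.
    """
    from shapely.geometry import Polygon as _Poly

    from .core import EmbryoTimeSeries

    cfg = series.config
    rng = np.random.default_rng(cfg.seed + 1)  # independent of growth noise
    snapshots = []
    for snap in series.snapshots:
        cells = []
        for cell in snap.cells:
            verts = cell.vertices
            sd = cfg.vertex_jitter_sd
            while sd > 0:
                cand = verts + rng.normal(0.0, sd, size=verts.shape)
                if _Poly(cand).is_valid:
                    verts = cand
                    break
                sd /= 2.0
            cells.append(CellOutline(cell.id, verts, cell.status))
        snapshots.append(EmbryoSnapshot(day=snap.day, cells=cells))
    return EmbryoTimeSeries(
        embryo_id=embryo_id,
        condition=condition,
        snapshots=snapshots,
        calibration=calibration,
        basal_end="min_axis",
    )


def render_snapshots(
    series: SimulatedSeries,
    calibration: float,
    embryo_id: str = "sim",
    condition: str = "CT8",
    path=None,
) -> bytes:
    """Render a simulated series to a segmentation SVG document.

    One group per snapshot (``d00`` …); each cell a closed path carrying its
    id; remnants filled grey. Inverse of :func:`kelpmorph.segio.read_segmentation`.
    """
    from .segio import write_segmentation

    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    if not series.snapshots:
        raise ValueError("empty series")
    ts = to_time_series(series, embryo_id, condition, calibration)
    return write_segmentation(ts, path=path)


def intact_config(**overrides) -> SimulationConfig:
    """Default intact-embryo configuration (no ablation, no noise)."""
    return replace(SimulationConfig(), **overrides)


def ablated_config(target: str, stage: int, **overrides) -> SimulationConfig:
    """Default configuration with an ablation of ``target`` at ``stage`` cells."""
    return replace(
        SimulationConfig(ablation=AblationPlan(target=target, stage=stage)),
        **overrides,
    )
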