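"""Domain containers for segmented kelp-embryo time-lapses.

An early *Saccharina* embryo is a monolayer of cells segmented once per day.
Each cell is stored as a closed simple polygon in micrometres; a snapshot is
one day's set of cells; a time series is an embryo's ordered snapshots plus
its experimental condition label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

#: Closed vocabulary of experimental conditions: intact controls (CT) and
#: apically (AE) / basally (BE) ablated embryos at the 2-, 4- or 8-cell stage.
CONDITIONS = ("CT2", "CT4", "CT8", "AE2", "AE4", "AE8", "BE2", "BE4", "BE8")


class CellStatus(str, Enum):
    ALIVE = "alive"
    ABLATED = "ablated"
    EXCLUDED = "excluded"


@dataclass
class CellOutline:
    """One cell at one time point.

    Parameters
    ----------
    id:
        Token unique within the snapshot.
    vertices:
        ``(n, 2)`` array of planar points in µm. The polygon is closed
        implicitly (the first vertex is not repeated). Stored counter-clockwise.
    status:
        ``alive`` for a living cell, ``ablated`` for a laser-ablation remnant
        (drawn grey in segmentations), ``excluded`` for cells removed from the
        analysis (e.g. the rhizoid-forming sub-basal cell).
    """

    id: str
    vertices: np.ndarray
    status: CellStatus = CellStatus.ALIVE

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"cell {self.id!r}: vertices must be (n, 2)")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError(f"cell {self.id!r}: polygon needs >= 3 vertices")
        if not np.isfinite(v).all():
            raise ValueError(f"cell {self.id!r}: non-finite vertex")
        self.vertices = v
        if not isinstance(self.status, CellStatus):
            self.status = CellStatus(self.status)

    @property
    def alive(self) -> bool:
        return self.status is CellStatus.ALIVE


@dataclass
class EmbryoSnapshot:
    """All segmented cells of one embryo on one day."""

    day: int
    cells: list[CellOutline] = field(default_factory=list)

    def __post_init__(self) -> None:
        # duplicate cell ids are reported by segio.validate_series, not here
        if self.day < 0:
            raise ValueError("day must be >= 0")

    @property
    def alive_cells(self) -> list[CellOutline]:
        return [c for c in self.cells if c.alive]

    @property
    def n_alive(self) -> int:
        return len(self.alive_cells)

    def __getitem__(self, cell_id: str) -> CellOutline:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass
class EmbryoTimeSeries:
    """An embryo's daily snapshot sequence with its condition label.

    ``calibration`` is the µm-per-drawing-unit factor of the source document;
    in-memory vertices are always already in µm. ``basal_end`` declares which
    end of the blade main axis is basal (``min_axis`` or ``max_axis``); it is
    metadata carried from the segmentation, never inferred from coordinates.
    """

    embryo_id: str
    condition: str
    snapshots: list[EmbryoSnapshot] = field(default_factory=list)
    calibration: float = 1.0
    basal_end: str = "min_axis"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")
        if self.basal_end not in ("min_axis", "max_axis"):
            raise ValueError("basal_end must be 'min_axis' or 'max_axis'")
        days = [s.day for s in self.snapshots]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"snapshot days not strictly increasing: {days}")

    @property
    def days(self) -> list[int]:
        return [s.day for s in self.snapshots]


def as_closed_ring(vertices: np.ndarray) -> np.ndarray:
    """Return the vertex array with the first point appended at the end."""
    v = np.asarray(vertices, dtype=float)
    return np.vstack([v, v[:1]])
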