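"""Cubic-lattice scaffold state: cell occupancy, continuous fields, geometry.

The scaffold is a cube of ``n_layers`` voxels per edge. An integer grid holds
one virtual-cell identifier per site (0 = empty); three float fields carry the
local glucose and oxygen concentrations (g/L) and the Young's modulus (kPa).
A well-mixed external medium reservoir (the culture medium above the scaffold)
is tracked alongside the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = ["CellRecord", "ScaffoldState", "neighbourhood", "manhattan_center_distance"]

# fixed neighbour order: -x, +x, -y, +y, -z, +z
_OFFSETS = ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1))


@dataclass
class CellRecord:
    """Per-virtual-cell bookkeeping.

    ``birth_iteration`` and ``last_division_iteration`` feed the AGE and TLD
    context variables; ``death_iteration`` is set exactly when the cell enters
    a dead-class type and feeds TD.
    """

    cell_id: int
    cell_type: str
    position: tuple[int, int, int]
    birth_iteration: int
    last_division_iteration: int
    death_iteration: Optional[int] = None


class ScaffoldState:
    """Mutable simulation state for one scaffold.

    Parameters
    ----------
    n_layers : int
        Voxels per edge (>= 3).
    voxel_size : float
        Edge length of one voxel in mm.
    glucose, oxygen : float
        Initial uniform concentrations in g/L.
    young_modulus : float
        Initial uniform stiffness in kPa.
    medium_glucose : float
        Glucose concentration of the external reservoir (g/L).
    medium_volume : float
        Volume of the external reservoir in mL.
    """

    def __init__(
        self,
        n_layers: int,
        voxel_size: float,
        glucose: float,
        oxygen: float,
        young_modulus: float,
        medium_glucose: float,
        medium_volume: float,
    ) -> None:
        if n_layers < 3:
            raise ValueError(f"n_layers must be >= 3, got {n_layers}")
        for name, v in (
            ("voxel_size", voxel_size),
            ("glucose", glucose),
            ("oxygen", oxygen),
            ("young_modulus", young_modulus),
            ("medium_glucose", medium_glucose),
            ("medium_volume", medium_volume),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if voxel_size <= 0 or young_modulus <= 0:
            raise ValueError("voxel_size and young_modulus must be positive")

        self.n_layers = int(n_layers)
        self.voxel_size = float(voxel_size)
        shape = (self.n_layers,) * 3
        self.cell_grid = np.zeros(shape, dtype=np.int64)
        self.glucose = np.full(shape, float(glucose))
        self.oxygen = np.full(shape, float(oxygen))
        self.young_modulus = np.full(shape, float(young_modulus))
        self.initial_young_modulus = float(young_modulus)
        self.medium_glucose = float(medium_glucose)
        self.medium_volume = float(medium_volume)
        self.cells: dict[int, CellRecord] = {}
        self._next_id = 1

    # -- geometry ---------------------------------------------------------

    @property
    def side(self) -> float:
        """Scaffold edge length in mm."""
        return self.n_layers * self.voxel_size

    @property
    def n_sites(self) -> int:
        return self.n_layers**3

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size**3

    @property
    def voxel_volume_l(self) -> float:
        # 1 mm^3 = 1e-6 L
        return self.voxel_volume_mm3 * 1e-6

    def in_bounds(self, position: tuple[int, int, int]) -> bool:
        return all(0 <= c < self.n_layers for c in position)

    # -- cell registry ----------------------------------------------------

    def add_cell(self, cell_type: str, position: tuple[int, int, int], iteration: int) -> CellRecord:
        """Place a new cell on an empty site and register it."""
        position = tuple(int(c) for c in position)
        if not self.in_bounds(position):
            raise IndexError(f"position {position} out of bounds")
        if self.cell_grid[position] != 0:
            raise ValueError(f"site {position} already occupied")
        rec = CellRecord(
            cell_id=self._next_id,
            cell_type=cell_type,
            position=position,
            birth_iteration=iteration,
            last_division_iteration=iteration,
        )
        self._next_id += 1
        self.cells[rec.cell_id] = rec
        self.cell_grid[position] = rec.cell_id
        return rec

    def move_cell(self, cell: CellRecord, target: tuple[int, int, int]) -> None:
        target = tuple(int(c) for c in target)
        if self.cell_grid[target] != 0:
            raise ValueError(f"target site {target} occupied")
        self.cell_grid[cell.position] = 0
        self.cell_grid[target] = cell.cell_id
        cell.position = target

    def remove_cell(self, cell: CellRecord) -> None:
        """Remove a (degraded) cell from the grid and the registry."""
        self.cell_grid[cell.position] = 0
        del self.cells[cell.cell_id]

    def iter_cells(self) -> Iterator[CellRecord]:
        return iter(self.cells.values())

    def count_by_type(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.cells.values():
            counts[rec.cell_type] = counts.get(rec.cell_type, 0) + 1
        return counts

    def check_consistency(self) -> None:
        """Registry <-> grid consistency (used by tests after every step)."""
        occupied = np.argwhere(self.cell_grid != 0)
        if len(occupied) != len(self.cells):
            raise AssertionError("grid occupancy differs from registry size")
        for rec in self.cells.values():
            if self.cell_grid[rec.position] != rec.cell_id:
                raise AssertionError(f"cell {rec.cell_id} grid/registry mismatch")


def neighbourhood(position: tuple[int, int, int], state: ScaffoldState) -> list[tuple[int, int, int]]:
    """Face-adjacent (6-connected) in-bounds neighbours of ``position``.

    Deterministic order (-x, +x, -y, +y, -z, +z), clipped at the boundary.
    """
    if not state.in_bounds(position):
        raise IndexError(f"position {position} out of bounds")
    x, y, z = position
    out = []
    for dx, dy, dz in _OFFSETS:
        q = (x + dx, y + dy, z + dz)
        if state.in_bounds(q):
            out.append(q)
    return out


def manhattan_center_distance(position: tuple[int, int, int], state: ScaffoldState) -> float:
    """L1 distance (mm) from a voxel center to the scaffold's geometric center.

    Voxel centers sit at (i + 0.5) * voxel_size; the center of the cube is at
    side/2 on each axis. The Manhattan metric replaces the Euclidean radius
    because the cubic lattice is not radially symmetric.
    """
    if not state.in_bounds(position):
        raise IndexError(f"position {position} out of bounds")
    c = state.side / 2.0
    return float(sum(abs((i + 0.5) * state.voxel_size - c) for i in position))
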