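"""Population scale factor and initial cell placement.

A wet-lab experiment seeds millions of biological cells; the lattice holds at
most one virtual cell per site. The occupancy scale factor maps the in-vitro
population onto the lattice while preserving the fraction of scaffold volume
initially occupied: with an average eukaryotic cell volume of 4.2e-6 mm^3,

    occupied_fraction = n_vitro * cell_volume / scaffold_volume
    n_virtual         = round(occupied_fraction * lattice_capacity)

and each virtual cell then aggregates ``n_vitro / n_virtual`` biological
cells. That aggregation ratio rescales the per-cell nutrient and oxygen
uptakes so the virtual population consumes what the real one would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lattice import ScaffoldState

__all__ = ["ScaleFactor", "compute_scale_factor", "seed_uniform", "DEFAULT_CELL_VOLUME_MM3"]

DEFAULT_CELL_VOLUME_MM3 = 4.2e-6


@dataclass(frozen=True)
class ScaleFactor:
    occupied_fraction: float
    n_virtual: int
    aggregation_ratio: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_scale_factor(
    n_vitro: float,
    cell_volume: float,
    scaffold_volume: float,
    capacity: int,
) -> ScaleFactor:
    """Occupancy scale factor between the in-vitro and virtual populations.

    ``capacity`` is the total lattice capacity (sites x capacity per site).
    ``n_virtual`` is rounded half-away-from-zero with a floor of 1.
    """
    if n_vitro <= 0:
        raise ValueError("n_vitro must be positive (request empty seeding explicitly)")
    if cell_volume <= 0 or scaffold_volume <= 0 or capacity <= 0:
        raise ValueError("cell_volume, scaffold_volume and capacity must be positive")
    fraction = n_vitro * cell_volume / scaffold_volume
    n_virtual = max(1, _round_half_away(fraction * capacity))
    return ScaleFactor(
        occupied_fraction=fraction,
        n_virtual=n_virtual,
        aggregation_ratio=n_vitro / n_virtual,
    )


def seed_uniform(
    state: ScaffoldState,
    n_virtual: int,
    composition: Mapping[str, float],
    rng: np.random.Generator,
) -> ScaffoldState:
    """Place ``n_virtual`` cells on distinct uniformly-random empty sites.

    Cell types are drawn multinomially from ``composition`` (fractions summing
    to 1). Placement is a seeded shuffle of the empty-site list — documented
    so other implementations can reproduce placements from the same stream.
    Cells are registered at iteration 0.
    """
    if n_virtual < 0:
        raise ValueError("n_virtual must be non-negative")
    fracs = dict(composition)
    total = sum(fracs.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"composition fractions must sum to 1, got {total}")
    if any(f < 0 for f in fracs.values()):
        raise ValueError("composition fractions must be non-negative")

    empty = np.argwhere(state.cell_grid == 0)
    if n_virtual > len(empty):
        raise ValueError(f"cannot place {n_virtual} cells on {len(empty)} empty sites")
    order = rng.permutation(len(empty))[:n_virtual]
    sites = empty[order]

    types = list(fracs)
    counts = rng.multinomial(n_virtual, [fracs[t] for t in types])
    assignment = np.repeat(np.arange(len(types)), counts)
    rng.shuffle(assignment)

    for site, ti in zip(sites, assignment):
        state.add_cell(types[int(ti)], tuple(int(c) for c in site), iteration=0)
    return state
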