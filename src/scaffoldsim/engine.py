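"""Simulation engine: the per-iteration loop and whole-run orchestration.

Each iteration advances the scaffold one protocol time step:

1. glucose and oxygen diffuse (Fick's second law, boundary exchange with the
   external medium);
2. the medium is replaced if a media change falls on this iteration (glucose
   reset everywhere, reservoir refilled);
3. every cell executes all environmental rules that apply to its type
   (nutrient/oxygen uptake scaled by the aggregation ratio, local matrix
   stiffening by proliferant cells);
4. every cell, visited in a freshly shuffled random order, selects at most
   one behavioural rule according to the evaluated probabilities (residual
   probability = stay) and executes it.

Runs are bitwise reproducible given (config, seed): one master generator
drives seeding, rule selection and visit order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .diffusion import DiffusionSpec, apply_media_change, diffusion_step
from .lattice import CellRecord, ScaffoldState, neighbourhood
from .rules import (
    EMPTY_TYPE,
    BehaviouralRule,
    EnvironmentalRule,
    build_context,
    evaluate_probability,
    parse_rule,
)
from .seeding import ScaleFactor, compute_scale_factor, seed_uniform

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "create_state",
    "apply_environmental_rules",
    "select_and_execute_behaviour",
    "run_iteration",
    "run_simulation",
    "run_replicates",
    "replicate_seed",
]

logger = logging.getLogger(__name__)

PARAMETER_NAMES = ("a", "b", "c", "d", "e", "U_Glu", "U_O2", "U_YM", "s", "lox")
CELL_CLASSES = ("proliferant", "quiescent", "dead")


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass
class SimulationConfig:
    """Complete description of one in-silico culture experiment.

    Parameters follow the model's coefficient set: ``a``–``e`` are the
    dimensionless multiplicative coefficients of the behavioural rules
    (doubling/degradation, quiescent-to-proliferant transition, death,
    proliferant-to-quiescent transition, migration); ``U_Glu`` and ``U_O2``
    are per-biological-cell uptakes in g/cell/h; ``U_YM`` is the reference
    stiffening increment in kPa/h per virtual cell; ``s`` scales quiescent
    consumption relative to proliferant; ``lox`` scales matrix cross-linking
    activity (the cell line's relative lysyl-oxidase expression).
    """

    # scaffold
    n_layers: int = 10
    side_mm: float = 10.0
    initial_young_modulus: float = 47.0
    capacity_per_site: int = 1
    # protocol
    total_hours: float = 240.0
    dt_hours: float = 1.0
    media_change_hours: float = 24.0
    medium_volume_ml: float = 1.0
    # population
    n_vitro: float = 5e6
    cell_volume_mm3: float = 4.2e-6
    composition: dict = field(default_factory=lambda: {"P": 1.0})
    # model definition
    cell_types: dict = field(default_factory=lambda: {"P": "proliferant", "Q": "quiescent", "D": "dead"})
    rule_lines: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    diffusion: DiffusionSpec = field(default_factory=DiffusionSpec)
    # run control
    seed: int = 0
    snapshot_hours: tuple = ()
    name: str = ""

    # -- derived ----------------------------------------------------------

    @property
    def voxel_size(self) -> float:
        return self.side_mm / self.n_layers

    @property
    def scaffold_volume_mm3(self) -> float:
        return self.side_mm**3

    @property
    def capacity(self) -> int:
        return self.n_layers**3 * self.capacity_per_site

    @property
    def n_iterations(self) -> int:
        return int(round(self.total_hours / self.dt_hours))

    def parsed_rules(self) -> list:
        types = set(self.cell_types)
        return [
            parse_rule(line, cell_types=types, constants=self.parameters)
            for line in self.rule_lines
        ]

    def validate(self) -> None:
        """Aggregate all semantic errors before any compute."""
        errors: list[str] = []
        if self.n_layers < 3:
            errors.append(f"scaffold resolution must be >= 3 layers, got {self.n_layers}")
        if self.side_mm <= 0 or self.initial_young_modulus <= 0:
            errors.append("scaffold side and initial stiffness must be positive")
        if self.dt_hours <= 0:
            errors.append("iteration length must be positive")
        if self.total_hours < 0:
            errors.append("total duration must be non-negative")
        if self.total_hours > 0 and abs(self.total_hours / self.dt_hours - self.n_iterations) > 1e-9:
            errors.append("total duration must be divisible by the iteration length")
        if self.n_vitro <= 0:
            errors.append("initial population must be positive")
        for cls in self.cell_types.values():
            if cls not in CELL_CLASSES:
                errors.append(f"unknown cell class {cls!r} (expected one of {CELL_CLASSES})")
        for t in self.composition:
            if t not in self.cell_types:
                errors.append(f"composition refers to undeclared cell type {t!r}")
        comp_total = sum(self.composition.values())
        if abs(comp_total - 1.0) > 1e-9:
            errors.append(f"composition fractions must sum to 1, got {comp_total}")
        for p in PARAMETER_NAMES:
            if p not in self.parameters:
                errors.append(f"missing parameter {p!r}")
        prm = self.parameters
        for p in ("a", "b", "c", "d", "e", "U_Glu", "U_O2", "U_YM", "lox"):
            if p in prm and prm[p] < 0:
                errors.append(f"parameter {p} must be non-negative, got {prm[p]}")
        if "s" in prm and not (0.0 <= prm["s"] <= 1.0):
            errors.append(f"parameter s must be in [0, 1], got {prm['s']}")
        try:
            rules = self.parsed_rules()
        except Exception as exc:  # rule syntax / unknown-type problems
            errors.append(str(exc))
            rules = []
        for r in rules:
            if isinstance(r, BehaviouralRule):
                if r.product_type == EMPTY_TYPE and r.extra_product is None:
                    if self.cell_types.get(r.source_type) != "dead":
                        errors.append(
                            f"rule {r.rule_id}: only dead-class cells may degrade to empty"
                        )
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))

    def config_hash(self) -> str:
        from .experiment_io import dump_config  # avoid import cycle at module load

        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Everything a run produces: per-iteration counts and field means, field
    snapshots at requested hours, the per-cell event log, and run metadata."""

    timeseries: pd.DataFrame
    snapshots: dict  # hour -> {"glucose"|"oxygen"|"young_modulus"|"cells": array}
    events: pd.DataFrame
    config_hash: str
    seed: int
    scale: ScaleFactor
    cell_types: dict
    initial_living: int
    final_state: Optional[ScaffoldState] = None

    @property
    def living_classes(self) -> tuple:
        return tuple(t for t, c in self.cell_types.items() if c in ("proliferant", "quiescent"))


# ---------------------------------------------------------------------------


def create_state(config: SimulationConfig) -> ScaffoldState:
    """Fresh scaffold: uniform fields at the fresh-media / incubator values
    and the configured initial stiffness, empty cell grid, full reservoir."""
    spec = config.diffusion
    return ScaffoldState(
        n_layers=config.n_layers,
        voxel_size=config.voxel_size,
        glucose=spec.media_glucose,
        oxygen=spec.incubator_oxygen,
        young_modulus=config.initial_young_modulus,
        medium_glucose=spec.media_glucose,
        medium_volume=config.medium_volume_ml,
    )


def apply_environmental_rules(
    state: ScaffoldState,
    env_rules: list,
    config: SimulationConfig,
    scale: ScaleFactor,
) -> None:
    """Execute every environmental rule for every cell of its source type.

    Uptakes are per biological cell, so one virtual cell consumes
    ``aggregation_ratio`` times the reference amount; quiescent-class cells
    consume a fraction ``s`` of that. Matrix stiffening applies the increment
    to the cell's voxel and its entire 6-neighbourhood, unscaled by the
    aggregation ratio (the increment is calibrated per virtual cell).
    """
    prm = config.parameters
    dt = config.dt_hours
    voxel_l = state.voxel_volume_l
    refs = {"Glc": prm["U_Glu"], "O2": prm["U_O2"], "YM": prm["U_YM"]}
    by_type: dict[str, list[EnvironmentalRule]] = {}
    for r in env_rules:
        by_type.setdefault(r.source_type, []).append(r)

    for cell in list(state.iter_cells()):
        rules_t = by_type.get(cell.cell_type)
        if not rules_t:
            continue
        cls = config.cell_types[cell.cell_type]
        m = prm["s"] if cls == "quiescent" else 1.0
        pos = cell.position
        for r in rules_t:
            amount = refs[r.tag] if r.amount == "U" else float(r.amount)
            if r.tag == "Glc":
                drop = scale.aggregation_ratio * amount * m * dt / voxel_l
                state.glucose[pos] = max(0.0, state.glucose[pos] - drop)
            elif r.tag == "O2":
                drop = scale.aggregation_ratio * amount * m * dt / voxel_l
                state.oxygen[pos] = max(0.0, state.oxygen[pos] - drop)
            else:  # YM
                # one equal share to the cell's voxel and each in-bounds
                # neighbour; shares of clipped (out-of-scaffold) neighbours
                # fall back onto the cell's own voxel, so every cell exerts
                # its full cross-linking effect on the matrix that exists
                inc = prm["lox"] * amount * dt
                if inc != 0.0:
                    nbrs = neighbourhood(pos, state)
                    state.young_modulus[pos] += inc * (7 - len(nbrs))
                    for q in nbrs:
                        state.young_modulus[q] += inc


def select_and_execute_behaviour(
    cell: CellRecord,
    state: ScaffoldState,
    rules_for_type: list,
    ctx,
    config: SimulationConfig,
    rng: np.random.Generator,
    iteration: int,
    events: list,
) -> None:
    """Draw at most one behavioural rule for ``cell`` and execute it.

    Probabilities are evaluated in ``ctx`` and clamped; when their sum
    exceeds 1 they are renormalized (and a warning logged once per run by
    the caller's filter) — residual probability means the cell keeps its
    state. Duplication and migration into a full neighbourhood are no-ops.
    """
    if not rules_for_type:
        return
    probs = [evaluate_probability(r, ctx, config.parameters) for r in rules_for_type]
    total = sum(probs)
    if total > 1.0:
        logger.warning(
            "probabilities for type %s sum to %.3f > 1; renormalizing (mis-calibrated rule set?)",
            cell.cell_type,
            total,
        )
        probs = [p / total for p in probs]
    u = rng.random()
    acc = 0.0
    chosen = None
    for r, p in zip(rules_for_type, probs):
        acc += p
        if u < acc:
            chosen = r
            break
    if chosen is None:
        return  # stay

    b, c_term = chosen.product_type, chosen.extra_product
    if c_term is not None and b != EMPTY_TYPE:
        # duplication: parent becomes B, daughter of type C on an empty neighbour
        empties = [q for q in neighbourhood(cell.position, state) if state.cell_grid[q] == 0]
        if not empties:
            return
        target = empties[int(rng.integers(len(empties)))]
        cell.cell_type = b
        cell.last_division_iteration = iteration
        daughter = state.add_cell(c_term, target, iteration)
        events.append((iteration, "birth", daughter.cell_id, c_term, *target, chosen.rule_id))
    elif c_term is not None and b == EMPTY_TYPE:
        # migration: cell vacates its site and moves as type C
        empties = [q for q in neighbourhood(cell.position, state) if state.cell_grid[q] == 0]
        if not empties:
            return
        target = empties[int(rng.integers(len(empties)))]
        state.move_cell(cell, target)
        if cell.cell_type != c_term:
            events.append((iteration, "transition", cell.cell_id, c_term, *target, chosen.rule_id))
        cell.cell_type = c_term
        events.append((iteration, "move", cell.cell_id, c_term, *target, chosen.rule_id))
    elif b == EMPTY_TYPE:
        # degradation (dead -> empty)
        events.append((iteration, "degrade", cell.cell_id, cell.cell_type, *cell.position, chosen.rule_id))
        state.remove_cell(cell)
    else:
        # in-place status change
        old = cell.cell_type
        if old != b:
            cell.cell_type = b
            if config.cell_types[b] == "dead" and config.cell_types.get(old) != "dead":
                cell.death_iteration = iteration
                events.append((iteration, "death", cell.cell_id, b, *cell.position, chosen.rule_id))
            else:
                events.append((iteration, "transition", cell.cell_id, b, *cell.position, chosen.rule_id))


def _media_change_due(config: SimulationConfig, iteration: int) -> bool:
    period = config.media_change_hours
    if period <= 0:
        return False
    hour = iteration * config.dt_hours
    k = hour / period
    return abs(k - round(k)) < 1e-9 and round(k) > 0


def run_iteration(
    state: ScaffoldState,
    config: SimulationConfig,
    scale: ScaleFactor,
    iteration: int,
    rng: np.random.Generator,
    events: list,
    env_rules: list,
    behavioural_by_type: dict,
) -> None:
    """One pass of the iteration loop (diffusion, media change, environmental
    rules, behavioural selection in shuffled order), mutating ``state``."""
    spec = config.diffusion
    dt = config.dt_hours

    state.glucose, state.medium_glucose = diffusion_step(
        state.glucose,
        spec.diffusivity_glucose,
        dt,
        state.voxel_size,
        spec.glucose_boundary,
        reservoir_concentration=state.medium_glucose,
        reservoir_volume_ml=state.medium_volume,
    )
    state.oxygen, _ = diffusion_step(
        state.oxygen,
        spec.diffusivity_oxygen,
        dt,
        state.voxel_size,
        spec.oxygen_boundary,
        reservoir_concentration=spec.incubator_oxygen,
    )

    if _media_change_due(config, iteration):
        apply_media_change(state, spec)

    # Cells sense the nutrient fields as relaxed by diffusion over the past
    # step, before this iteration's uptake impulses. A virtual cell aggregates
    # a whole voxel's worth of biological cells, so its own hourly uptake
    # transiently empties the voxel; the post-uptake value reflects that
    # numerical impulse, not the concentration the cells grew in.
    sensed_glucose = state.glucose.copy()
    sensed_oxygen = state.oxygen.copy()

    apply_environmental_rules(state, env_rules, config, scale)

    ids = np.array(sorted(state.cells), dtype=np.int64)
    rng.shuffle(ids)
    total_iters = max(config.n_iterations, 1)
    for cid in ids:
        cell = state.cells.get(int(cid))
        if cell is None:  # degraded earlier this iteration
            continue
        ctx = build_context(
            cell,
            state,
            iteration,
            total_iters,
            media_glucose=spec.media_glucose,
            incubator_oxygen=spec.incubator_oxygen,
            capacity=config.capacity,
            glucose_field=sensed_glucose,
            oxygen_field=sensed_oxygen,
        )
        select_and_execute_behaviour(
            cell,
            state,
            behavioural_by_type.get(cell.cell_type, ()),
            ctx,
            config,
            rng,
            iteration,
            events,
        )


def _timeseries_row(state: ScaffoldState, config: SimulationConfig, iteration: int) -> dict:
    counts = state.count_by_type()
    row = {"iteration": iteration, "hour": iteration * config.dt_hours}
    for t in config.cell_types:
        row[f"n_{t}"] = counts.get(t, 0)
    row["mean_glucose"] = float(state.glucose.mean())
    row["mean_oxygen"] = float(state.oxygen.mean())
    row["mean_young_modulus"] = float(state.young_modulus.mean())
    row["reservoir_glucose"] = state.medium_glucose
    return row


def _snapshot(state: ScaffoldState) -> dict:
    return {
        "glucose": state.glucose.copy(),
        "oxygen": state.oxygen.copy(),
        "young_modulus": state.young_modulus.copy(),
        "cells": state.cell_grid.copy(),
    }


def run_simulation(config: SimulationConfig, keep_final_state: bool = True) -> SimulationResult:
    """Seed the scaffold and run the full protocol.

    Bitwise reproducible for a given (config, seed). A zero-hour protocol
    returns only the initial state.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = create_state(config)
    scale = compute_scale_factor(
        config.n_vitro, config.cell_volume_mm3, config.scaffold_volume_mm3, config.capacity
    )
    seed_uniform(state, scale.n_virtual, config.composition, rng)

    all_rules = config.parsed_rules()
    env_rules = [r for r in all_rules if isinstance(r, EnvironmentalRule)]
    behavioural_by_type: dict[str, list] = {}
    for r in all_rules:
        if isinstance(r, BehaviouralRule):
            behavioural_by_type.setdefault(r.source_type, []).append(r)

    events: list[tuple] = [
        (0, "birth", rec.cell_id, rec.cell_type, *rec.position, "seed")
        for rec in sorted(state.iter_cells(), key=lambda r: r.cell_id)
    ]
    rows = [_timeseries_row(state, config, 0)]
    snapshots: dict[float, dict] = {}
    snap_hours = set(float(h) for h in config.snapshot_hours)
    if 0.0 in snap_hours:
        snapshots[0.0] = _snapshot(state)

    initial_living = sum(
        1 for rec in state.iter_cells() if config.cell_types[rec.cell_type] != "dead"
    )

    for iteration in range(1, config.n_iterations + 1):
        run_iteration(state, config, scale, iteration, rng, events, env_rules, behavioural_by_type)
        rows.append(_timeseries_row(state, config, iteration))
        hour = iteration * config.dt_hours
        if hour in snap_hours:
            snapshots[hour] = _snapshot(state)

    events_df = pd.DataFrame(
        events, columns=["iteration", "event", "cell_id", "cell_type", "x", "y", "z", "rule_id"]
    )
    return SimulationResult(
        timeseries=pd.DataFrame(rows),
        snapshots=snapshots,
        events=events_df,
        config_hash=config.config_hash(),
        seed=config.seed,
        scale=scale,
        cell_types=dict(config.cell_types),
        initial_living=initial_living,
        final_state=state if keep_final_state else None,
    )


def replicate_seed(base_seed: int, k: int) -> int:
    """Deterministic, platform-stable seed for replicate ``k`` (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), int(k)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    base_seed: int,
    keep_final_state: bool = True,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent simulations; replicate ``k`` uses a
    seed derived deterministically from ``(base_seed, k)``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    results = []
    for k in range(n_replicates):
        cfg = replace_seed(config, replicate_seed(base_seed, k))
        results.append(run_simulation(cfg, keep_final_state=keep_final_state))
    return results


def replace_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    import copy

    cfg = copy.copy(config)
    cfg.seed = int(seed)
    return cfg
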