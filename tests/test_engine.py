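"""Iteration loop: environmental uptake, behavioural selection, whole runs."""

import numpy as np
import pytest

from scaffoldsim import create_state, run_replicates, run_simulation
from scaffoldsim.engine import (
    ConfigError,
    apply_environmental_rules,
    replicate_seed,
    run_iteration,
    select_and_execute_behaviour,
)
from scaffoldsim.rules import BehaviouralRule, EnvironmentalRule, build_context, parse_rule
from scaffoldsim.seeding import ScaleFactor, compute_scale_factor

from conftest import make_config


def env_rules_of(config):
    return [r for r in config.parsed_rules() if isinstance(r, EnvironmentalRule)]


def behavioural_of(config):
    by_type = {}
    for r in config.parsed_rules():
        if isinstance(r, BehaviouralRule):
            by_type.setdefault(r.source_type, []).append(r)
    return by_type


class TestEnvironmentalRules:
    def test_single_proliferant_glucose_drop_matches_reference_uptake(self):
        """2.381e5 aggregated cells x 16.7e-12 g/cell/h in a 1 mm^3 voxel
        deplete local glucose by ~3.98 g/L in one hour."""
        cfg = make_config(n_layers=10, side_mm=10.0)
        state = create_state(cfg)
        state.add_cell("P", (5, 5, 5), 0)
        scale = compute_scale_factor(5e6, 4.2e-6, 1000.0, 1000)
        apply_environmental_rules(state, env_rules_of(cfg), cfg, scale)
        drop = 4.5 - state.glucose[5, 5, 5]
        assert drop == pytest.approx(scale.aggregation_ratio * 16.7e-12 / 1e-6, rel=1e-12)
        assert drop == pytest.approx(3.976, abs=0.005)

    def test_uptake_floors_at_zero(self):
        cfg = make_config(n_layers=10, side_mm=10.0)
        state = create_state(cfg)
        state.glucose[:] = 0.5  # less than one hour's demand
        state.add_cell("P", (5, 5, 5), 0)
        scale = compute_scale_factor(5e6, 4.2e-6, 1000.0, 1000)
        apply_environmental_rules(state, env_rules_of(cfg), cfg, scale)
        assert state.glucose[5, 5, 5] == 0.0
        assert np.all(state.glucose >= 0)

    def test_quiescent_cell_consumes_fraction_s(self):
        cfg = make_config(n_layers=10, side_mm=10.0, parameters={"s": 0.5})
        state = create_state(cfg)
        state.add_cell("P", (2, 2, 2), 0)
        state.add_cell("Q", (7, 7, 7), 0)
        scale = ScaleFactor(0.021, 21, 1e5)
        apply_environmental_rules(state, env_rules_of(cfg), cfg, scale)
        drop_p = 4.5 - state.glucose[2, 2, 2]
        drop_q = 4.5 - state.glucose[7, 7, 7]
        assert drop_q == pytest.approx(0.5 * drop_p, rel=1e-12)
        o2_p = cfg.diffusion.incubator_oxygen - state.oxygen[2, 2, 2]
        o2_q = cfg.diffusion.incubator_oxygen - state.oxygen[7, 7, 7]
        assert o2_q == pytest.approx(0.5 * o2_p, rel=1e-12)

    def test_stiffening_conserves_per_cell_total_effect(self):
        cfg = make_config(n_layers=10, side_mm=10.0,
                          parameters={"lox": 1e-3, "U_YM": 10.0})
        scale = ScaleFactor(0.021, 21, 1e5)
        for pos in [(5, 5, 5), (0, 0, 0)]:  # interior and corner
            state = create_state(cfg)
            state.add_cell("P", pos, 0)
            apply_environmental_rules(state, env_rules_of(cfg), cfg, scale)
            added = state.young_modulus.sum() - 47.0 * state.n_sites
            assert added == pytest.approx(7 * 1e-3 * 10.0, rel=1e-9)
        # corner voxel absorbs the clipped shares
        assert state.young_modulus[0, 0, 0] - 47.0 == pytest.approx(4 * 1e-2, rel=1e-9)

    def test_zero_lox_leaves_stiffness_untouched_all_run(self):
        cfg = make_config(parameters={"lox": 0.0}, total_hours=12.0, media_change_hours=12.0)
        res = run_simulation(cfg)
        assert np.all(res.final_state.young_modulus == 47.0)


class TestBehaviouralSelection:
    def make_state_with_cell(self, cell_type="P", pos=(2, 2, 2)):
        cfg = make_config()
        state = create_state(cfg)
        cell = state.add_cell(cell_type, pos, 0)
        return cfg, state, cell

    def ctx_for(self, cell, state, cfg, iteration=1):
        return build_context(cell, state, iteration, cfg.n_iterations,
                             media_glucose=cfg.diffusion.media_glucose,
                             incubator_oxygen=cfg.diffusion.incubator_oxygen,
                             capacity=cfg.capacity)

    def test_all_zero_probabilities_leave_state_unchanged(self):
        cfg, state, cell = self.make_state_with_cell()
        rules = [parse_rule("r: P -> Q, 0.0", cell_types={"P", "Q", "D"})]
        events = []
        select_and_execute_behaviour(cell, state, rules, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 1, events)
        assert cell.cell_type == "P" and not events

    def test_blocked_duplication_is_noop(self):
        cfg = make_config(n_layers=3, side_mm=3.0)
        state = create_state(cfg)
        center = (1, 1, 1)
        for x in range(3):
            for y in range(3):
                for z in range(3):
                    state.add_cell("P", (x, y, z), 0)
        cell = state.cells[state.cell_grid[center]]
        rules = [parse_rule("dup: P -> P + P, 1.0", cell_types={"P", "Q", "D"})]
        events = []
        select_and_execute_behaviour(cell, state, rules, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 1, events)
        assert len(state.cells) == 27 and cell.last_division_iteration == 0
        assert not events

    def test_duplication_places_daughter_on_empty_neighbour(self):
        cfg, state, cell = self.make_state_with_cell()
        rules = [parse_rule("dup: P -> P + P, 1.0", cell_types={"P", "Q", "D"})]
        events = []
        select_and_execute_behaviour(cell, state, rules, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 3, events)
        assert len(state.cells) == 2
        daughter = next(c for c in state.iter_cells() if c.cell_id != cell.cell_id)
        assert daughter.birth_iteration == 3
        assert cell.last_division_iteration == 3
        assert sum(abs(a - b) for a, b in zip(daughter.position, cell.position)) == 1
        state.check_consistency()

    def test_migration_relocates_without_copy(self):
        cfg, state, cell = self.make_state_with_cell()
        rules = [parse_rule("mv: P -> empty + P, 1.0", cell_types={"P", "Q", "D"})]
        old_pos = cell.position
        select_and_execute_behaviour(cell, state, rules, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 1, [])
        assert len(state.cells) == 1
        assert cell.position != old_pos
        assert state.cell_grid[old_pos] == 0
        state.check_consistency()

    def test_death_records_iteration_and_degradation_removes(self):
        cfg, state, cell = self.make_state_with_cell("Q")
        die = [parse_rule("die: Q -> D, 1.0", cell_types={"P", "Q", "D"})]
        select_and_execute_behaviour(cell, state, die, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 5, [])
        assert cell.cell_type == "D" and cell.death_iteration == 5
        clear = [parse_rule("clear: D -> empty, 1.0", cell_types={"P", "Q", "D"})]
        select_and_execute_behaviour(cell, state, clear, self.ctx_for(cell, state, cfg),
                                     cfg, np.random.default_rng(0), 6, [])
        assert not state.cells and state.cell_grid[2, 2, 2] == 0

    def test_oversubscribed_probabilities_renormalize(self):
        cfg, state, cell = self.make_state_with_cell()
        rules = [parse_rule("r1: P -> Q, 0.9", cell_types={"P", "Q", "D"}),
                 parse_rule("r2: P -> D, 0.9", cell_types={"P", "Q", "D"})]
        # sum = 1.8 > 1: one of the two rules must fire
        outcomes = set()
        for seed in range(10):
            cfg2, state2, cell2 = self.make_state_with_cell()
            select_and_execute_behaviour(cell2, state2, rules,
                                         self.ctx_for(cell2, state2, cfg2),
                                         cfg2, np.random.default_rng(seed), 1, [])
            outcomes.add(cell2.cell_type)
        assert outcomes <= {"Q", "D"} and outcomes


class TestRunIteration:
    def test_empty_scaffold_at_media_concentration_is_fixed_point(self):
        cfg = make_config()
        state = create_state(cfg)
        scale = ScaleFactor(0.0, 0, 1.0)
        run_iteration(state, cfg, scale, 1, np.random.default_rng(0), [],
                      env_rules_of(cfg), behavioural_of(cfg))
        assert np.allclose(state.glucose, 4.5, atol=1e-12)
        assert np.allclose(state.oxygen, cfg.diffusion.incubator_oxygen, atol=1e-15)
        assert not state.cells

    def test_media_change_resets_interior_despite_depletion(self):
        cfg = make_config(media_change_hours=1.0)  # change due every iteration
        state = create_state(cfg)
        state.glucose[:] = 0.05
        state.medium_glucose = 0.2
        scale = ScaleFactor(0.0, 0, 1.0)
        run_iteration(state, cfg, scale, 1, np.random.default_rng(0), [],
                      env_rules_of(cfg), behavioural_of(cfg))
        assert np.all(state.glucose == 4.5)
        assert state.medium_glucose == 4.5


class TestRunSimulation:
    def test_default_run_bookkeeping(self, tiny_config):
        res = run_simulation(tiny_config)
        assert len(res.timeseries) == tiny_config.n_iterations + 1
        assert res.timeseries["n_P"].iloc[0] == res.initial_living
        assert res.seed == tiny_config.seed

    def test_zero_hour_protocol_returns_initial_state_only(self):
        cfg = make_config(total_hours=0.0)
        res = run_simulation(cfg)
        assert len(res.timeseries) == 1
        assert (res.events["event"] == "birth").all()

    def test_bitwise_reproducible_for_config_and_seed(self, tiny_config):
        r1 = run_simulation(tiny_config)
        r2 = run_simulation(tiny_config)
        assert r1.timeseries.equals(r2.timeseries)
        assert r1.events.equals(r2.events)
        assert np.array_equal(r1.final_state.young_modulus, r2.final_state.young_modulus)

    def test_young_modulus_never_decreases(self):
        cfg = make_config(total_hours=48.0, snapshot_hours=tuple(float(h) for h in range(0, 49, 12)))
        res = run_simulation(cfg)
        hours = sorted(res.snapshots)
        for h0, h1 in zip(hours, hours[1:]):
            diff = res.snapshots[h1]["young_modulus"] - res.snapshots[h0]["young_modulus"]
            assert np.all(diff >= -1e-12)

    def test_cell_identities_have_consistent_life_histories(self, tiny_config):
        res = run_simulation(tiny_config)
        ev = res.events
        for cid, g in ev.groupby("cell_id"):
            kinds = list(g.sort_values("iteration")["event"])
            assert kinds.count("birth") == 1 and kinds[0] == "birth"
            assert kinds.count("death") <= 1
            assert kinds.count("degrade") <= 1
            if "degrade" in kinds:
                assert kinds[-1] == "degrade"
                assert "death" in kinds  # only dead cells degrade

    def test_zero_flux_glucose_mass_balance_equals_cell_uptake(self):
        """With a closed glucose boundary and no media change, the scaffold's
        glucose mass drop equals the summed uptake of the cells exactly."""
        from scaffoldsim import DiffusionSpec

        cfg = make_config(
            total_hours=6.0,
            media_change_hours=0.0,  # disabled
            parameters={"U_Glu": 1e-13, "a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0,
                        "e": 0.0, "lox": 0.0},
            diffusion=DiffusionSpec(glucose_boundary="zero-flux"),
        )
        res = run_simulation(cfg)
        ts = res.timeseries
        voxl = (cfg.voxel_size ** 3) * 1e-6
        mass0 = ts["mean_glucose"].iloc[0] * cfg.n_layers**3 * voxl
        mass1 = ts["mean_glucose"].iloc[-1] * cfg.n_layers**3 * voxl
        n_cells = res.initial_living  # frozen population (all rates zero)
        expected = n_cells * res.scale.aggregation_ratio * 1e-13 * 6.0
        assert mass0 - mass1 == pytest.approx(expected, rel=1e-9)

    def test_invalid_config_rejected_before_compute(self):
        cfg = make_config(total_hours=10.0, dt_hours=3.0)  # not divisible
        with pytest.raises(ConfigError):
            run_simulation(cfg)


class TestReplicates:
    def test_replicate_seeds_deterministic_and_below_2_31(self):
        seeds = [replicate_seed(123, k) for k in range(20)]
        assert seeds == [replicate_seed(123, k) for k in range(20)]
        assert len(set(seeds)) == 20
        assert all(0 <= s < 2**31 for s in seeds)

    def test_identical_batches_reproduce(self, tiny_config):
        a = run_replicates(tiny_config, 3, base_seed=9)
        b = run_replicates(tiny_config, 3, base_seed=9)
        for ra, rb in zip(a, b):
            assert ra.timeseries.equals(rb.timeseries)

    def test_deterministic_outputs_have_zero_variance_across_replicates(self, tiny_config):
        results = run_replicates(tiny_config, 4, base_seed=1)
        initial = [r.timeseries["n_P"].iloc[0] for r in results]
        assert np.var(initial) == 0.0
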