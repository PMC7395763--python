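import numpy as np
import pytest

from scaffoldsim import DiffusionSpec, ScaffoldState, SimulationConfig


DEFAULT_RULES = [
    "dup: P -> P + P, a * min(Glc, O2) / 24",
    "rest: P -> Q, d * (1 - min(Glc, O2))",
    "wake: Q -> P, b * Glc",
    "die: Q -> D, c * (1 - min(Glc, O2))",
    "move: P -> empty + P, e",
    "clear: D -> empty, a / 24",
    "glc_p: P -> U, environment(Glc)",
    "glc_q: Q -> U, environment(Glc)",
    "o2_p: P -> U, environment(O2)",
    "o2_q: Q -> U, environment(O2)",
    "stiffen: P -> U, environment(YM)",
]

DEFAULT_PARAMS = {
    "a": 0.44,
    "b": 0.02,
    "c": 0.05,
    "d": 0.05,
    "e": 0.01,
    "U_Glu": 16.7e-12,
    "U_O2": 2.93e-15,
    "U_YM": 30.0,
    "s": 0.5,
    "lox": 3e-3,
}


def make_config(**overrides) -> SimulationConfig:
    """Small, fast configuration factory for tests (5^3 lattice, 24 h)."""
    params = dict(DEFAULT_PARAMS)
    params.update(overrides.pop("parameters", {}))
    defaults = dict(
        n_layers=5,
        side_mm=5.0,
        initial_young_modulus=47.0,
        total_hours=24.0,
        dt_hours=1.0,
        media_change_hours=24.0,
        medium_volume_ml=3.0,
        n_vitro=5e6,
        cell_volume_mm3=4.2e-6,
        composition={"P": 1.0},
        cell_types={"P": "proliferant", "Q": "quiescent", "D": "dead"},
        rule_lines=list(DEFAULT_RULES),
        parameters=params,
        diffusion=DiffusionSpec(),
        seed=0,
        snapshot_hours=(),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    return make_config()


@pytest.fixture
def empty_state() -> ScaffoldState:
    return ScaffoldState(
        n_layers=10,
        voxel_size=1.0,
        glucose=4.5,
        oxygen=7.2e-3,
        young_modulus=47.0,
        medium_glucose=4.5,
        medium_volume=3.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
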