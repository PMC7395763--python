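"""Configuration files, shipped presets and structured-text output.

The configuration dialect is INI-style: ``key = value`` entries in the
sections ``[scaffold] [protocol] [population] [celltypes] [rules]
[parameters] [diffusion] [output]``. The ``[rules]`` section holds one rule
statement per line (``id : A -> B [+ C], D``); ``#`` starts a comment.
Numbers accept scientific notation. Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import configparser
import io
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .diffusion import DiffusionSpec
from .engine import ConfigError, SimulationConfig, SimulationResult

__all__ = ["load_config", "loads_config", "dump_config", "write_results", "load_preset", "available_presets"]

_SECTION_KEYS = {
    "scaffold": {"n_layers", "side_mm", "young_modulus_kpa", "capacity_per_site"},
    "protocol": {"duration_h", "dt_h", "media_change_h", "medium_volume_ml"},
    "population": {"initial_cells", "cell_volume_mm3", "composition"},
    "diffusion": {
        "d_glucose_mm2_h",
        "d_oxygen_mm2_h",
        "media_glucose_g_l",
        "incubator_oxygen_g_l",
        "glucose_boundary",
        "oxygen_boundary",
    },
    "output": {"snapshot_hours", "seed", "name"},
}


def _parser() -> configparser.ConfigParser:
    p = configparser.ConfigParser(
        delimiters=("=", ":"),
        comment_prefixes=("#",),
        inline_comment_prefixes=("#",),
        interpolation=None,
        strict=True,
    )
    p.optionxform = str  # preserve case: cell types and parameter names are case-sensitive
    return p


def loads_config(text: str, name: str = "<string>") -> SimulationConfig:
    """Parse a configuration from text. See :func:`load_config`."""
    p = _parser()
    try:
        p.read_string(text, source=name)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {name}: {exc}") from exc

    errors: list[str] = []
    cfg = SimulationConfig()
    cfg.name = name

    def getnum(section, key, default=None, kind=float):
        if not p.has_option(section, key):
            if default is None:
                errors.append(f"[{section}] missing required key {key!r}")
                return 0
            return default
        raw = p.get(section, key)
        try:
            return kind(float(raw)) if kind is int else kind(raw)
        except ValueError:
            errors.append(f"[{section}] {key} = {raw!r} is not a number")
            return default if default is not None else 0

    for section in p.sections():
        if section in _SECTION_KEYS:
            unknown = set(p.options(section)) - _SECTION_KEYS[section]
            if unknown:
                errors.append(f"[{section}] unknown keys: {sorted(unknown)}")
        elif section not in ("celltypes", "rules", "parameters"):
            errors.append(f"unknown section [{section}]")

    if p.has_section("scaffold"):
        cfg.n_layers = getnum("scaffold", "n_layers", 10, int)
        cfg.side_mm = getnum("scaffold", "side_mm", 10.0)
        cfg.initial_young_modulus = getnum("scaffold", "young_modulus_kpa", 47.0)
        cfg.capacity_per_site = getnum("scaffold", "capacity_per_site", 1, int)
    if p.has_section("protocol"):
        cfg.total_hours = getnum("protocol", "duration_h", 240.0)
        cfg.dt_hours = getnum("protocol", "dt_h", 1.0)
        cfg.media_change_hours = getnum("protocol", "media_change_h", 24.0)
        cfg.medium_volume_ml = getnum("protocol", "medium_volume_ml", 1.0)
    if p.has_section("population"):
        cfg.n_vitro = getnum("population", "initial_cells")
        cfg.cell_volume_mm3 = getnum("population", "cell_volume_mm3", 4.2e-6)
        if p.has_option("population", "composition"):
            comp: dict[str, float] = {}
            for part in p.get("population", "composition").split(","):
                part = part.strip()
                if not part:
                    continue
                if ":" not in part:
                    errors.append(f"composition entry {part!r} is not 'type:fraction'")
                    continue
                t, frac = part.split(":", 1)
                try:
                    comp[t.strip()] = float(frac)
                except ValueError:
                    errors.append(f"composition fraction {frac!r} is not a number")
            cfg.composition = comp

    if p.has_section("celltypes"):
        cfg.cell_types = {t: p.get("celltypes", t).strip() for t in p.options("celltypes")}
    if p.has_section("parameters"):
        prm = {}
        for k in p.options("parameters"):
            try:
                prm[k] = float(p.get("parameters", k))
            except ValueError:
                errors.append(f"[parameters] {k} is not a number")
        cfg.parameters = prm
    if p.has_section("rules"):
        cfg.rule_lines = [
            f"{rid}: {p.get('rules', rid).strip()}" for rid in p.options("rules")
        ]

    if p.has_section("diffusion"):
        try:
            cfg.diffusion = DiffusionSpec(
                diffusivity_glucose=getnum("diffusion", "d_glucose_mm2_h", 2.412),
                diffusivity_oxygen=getnum("diffusion", "d_oxygen_mm2_h", 10.8),
                media_glucose=getnum("diffusion", "media_glucose_g_l", 4.5),
                incubator_oxygen=getnum("diffusion", "incubator_oxygen_g_l", 7.2e-3),
                glucose_boundary=p.get("diffusion", "glucose_boundary", fallback="reservoir").strip(),
                oxygen_boundary=p.get("diffusion", "oxygen_boundary", fallback="dirichlet").strip(),
            )
        except ValueError as exc:
            errors.append(str(exc))
    if p.has_section("output"):
        cfg.seed = getnum("output", "seed", 0, int)
        if p.has_option("output", "name"):
            cfg.name = p.get("output", "name").strip()
        if p.has_option("output", "snapshot_hours"):
            raw = p.get("output", "snapshot_hours")
            try:
                cfg.snapshot_hours = tuple(float(x) for x in raw.split(",") if x.strip())
            except ValueError:
                errors.append(f"[output] snapshot_hours {raw!r} is not a comma-separated number list")

    if errors:
        raise ConfigError(f"invalid configuration {name}:\n  - " + "\n  - ".join(errors))
    cfg.validate()
    return cfg


def load_config(path) -> SimulationConfig:
    """Load and fully validate a configuration file.

    Raises :class:`ConfigError` with every parse and semantic problem
    aggregated into one message.
    """
    path = Path(path)
    return loads_config(path.read_text(), name=path.name)


def dump_config(config: SimulationConfig) -> str:
    """Serialize a configuration to its canonical INI text (round-trips
    through :func:`loads_config`)."""
    buf = io.StringIO()
    d = config.diffusion
    comp = ", ".join(f"{t}:{f!r}" for t, f in config.composition.items())
    buf.write("[scaffold]\n")
    buf.write(f"n_layers = {config.n_layers}\n")
    buf.write(f"side_mm = {config.side_mm!r}\n")
    buf.write(f"young_modulus_kpa = {config.initial_young_modulus!r}\n")
    buf.write(f"capacity_per_site = {config.capacity_per_site}\n\n")
    buf.write("[protocol]\n")
    buf.write(f"duration_h = {config.total_hours!r}\n")
    buf.write(f"dt_h = {config.dt_hours!r}\n")
    buf.write(f"media_change_h = {config.media_change_hours!r}\n")
    buf.write(f"medium_volume_ml = {config.medium_volume_ml!r}\n\n")
    buf.write("[population]\n")
    buf.write(f"initial_cells = {config.n_vitro!r}\n")
    buf.write(f"cell_volume_mm3 = {config.cell_volume_mm3!r}\n")
    buf.write(f"composition = {comp}\n\n")
    buf.write("[celltypes]\n")
    for t, cls in config.cell_types.items():
        buf.write(f"{t} = {cls}\n")
    buf.write("\n[rules]\n")
    for line in config.rule_lines:
        buf.write(line + "\n")
    buf.write("\n[parameters]\n")
    for k, v in config.parameters.items():
        buf.write(f"{k} = {v!r}\n")
    buf.write("\n[diffusion]\n")
    buf.write(f"d_glucose_mm2_h = {d.diffusivity_glucose!r}\n")
    buf.write(f"d_oxygen_mm2_h = {d.diffusivity_oxygen!r}\n")
    buf.write(f"media_glucose_g_l = {d.media_glucose!r}\n")
    buf.write(f"incubator_oxygen_g_l = {d.incubator_oxygen!r}\n")
    buf.write(f"glucose_boundary = {d.glucose_boundary}\n")
    buf.write(f"oxygen_boundary = {d.oxygen_boundary}\n\n")
    buf.write("[output]\n")
    buf.write(f"seed = {config.seed}\n")
    if config.name:
        buf.write(f"name = {config.name}\n")
    if config.snapshot_hours:
        buf.write("snapshot_hours = " + ", ".join(repr(h) for h in config.snapshot_hours) + "\n")
    return buf.getvalue()


# -- shipped presets --------------------------------------------------------


def available_presets() -> list[str]:
    files = resources.files("scaffoldsim") / "presets"
    return sorted(f.name[: -len(".cfg")] for f in files.iterdir() if f.name.endswith(".cfg"))


def load_preset(name: str) -> SimulationConfig:
    """Load one of the shipped default configurations (e.g. ``mcf7``,
    ``mdamb231``, ``mdamb231_625k``)."""
    res = resources.files("scaffoldsim") / "presets" / f"{name}.cfg"
    if not res.is_file():
        raise ConfigError(f"unknown preset {name!r}; available: {available_presets()}")
    return loads_config(res.read_text(), name=name)


# -- output writing ---------------------------------------------------------


def write_results(result: SimulationResult, out_dir, version: str | None = None) -> list[Path]:
    """Write a run to structured text files.

    Produces ``timeseries.tsv`` (one row per iteration), ``events.tsv``
    (per-cell event log), one ``snapshots/<field>_<hour>.tsv`` per stored
    field snapshot (columns x, y, z, value; 0-based voxel indices) and a
    ``manifest.json`` with the config hash, seed and tool version. Output is
    byte-stable for identical inputs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ts_path = out / "timeseries.tsv"
    result.timeseries.to_csv(ts_path, sep="\t", index=False, float_format="%.10g")
    written.append(ts_path)

    ev_path = out / "events.tsv"
    result.events.to_csv(ev_path, sep="\t", index=False)
    written.append(ev_path)

    if result.snapshots:
        snap_dir = out / "snapshots"
        snap_dir.mkdir(exist_ok=True)
        for hour in sorted(result.snapshots):
            for field_name, arr in sorted(result.snapshots[hour].items()):
                n = arr.shape[0]
                idx = pd.MultiIndex.from_product([range(n)] * 3, names=["x", "y", "z"])
                df = pd.DataFrame({"value": arr.reshape(-1)}, index=idx).reset_index()
                path = snap_dir / f"{field_name}_{hour:g}.tsv"
                df.to_csv(path, sep="\t", index=False, float_format="%.10g")
                written.append(path)

    manifest = {
        "config_hash": result.config_hash,
        "seed": result.seed,
        "version": version or __version__,
        "n_virtual": result.scale.n_virtual,
        "aggregation_ratio": result.scale.aggregation_ratio,
        "cell_types": result.cell_types,
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)
    return written
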