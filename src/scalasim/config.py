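"""Run configuration: schema-validated loading, dumping and hashing.

A run is fully described by a :class:`RunConfig`: geometry parameters, array
spec, conductivity table, mesh options, solver settings, protocol selection
and output location.  Configs load from YAML or JSON; an empty file yields
the pure defaults (tissue conductivities per the built-in table, 34 uA
injected current).  Unknown keys are rejected by name, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import yaml

from .conductivity import DEFAULT_SIGMA_S_PER_M, DEFAULT_STRIA_THICKNESS_M, ConductivityTable
from .geometry import CochleaParams, ElectrodeArraySpec
from .meshing import MeshOptions
from .protocols import config_hash

__all__ = [
    "ConfigError",
    "SolverSettings",
    "ProtocolSettings",
    "Seeds",
    "RunConfig",
    "load_config",
    "dump_config",
    "run_config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema."""


@dataclass(frozen=True)
class SolverSettings:
    """Linear-solver and source-model settings."""

    method: str = "direct"
    tol: float = 1e-10
    max_iter: int = 5000
    contact_mode: str = "equipotential"
    inactive_mode: str = "float"
    ground_label: str = "GROUND_OUTER"
    injected_current_A: float = 34e-6

    def __post_init__(self) -> None:
        if self.method not in ("direct", "cg"):
            raise ConfigError("solver.method must be 'direct' or 'cg'")
        if self.contact_mode not in ("equipotential", "uniform_current"):
            raise ConfigError(
                "solver.contact_mode must be 'equipotential' or 'uniform_current'"
            )
        if self.inactive_mode not in ("float", "grounded"):
            raise ConfigError("solver.inactive_mode must be 'float' or 'grounded'")
        if not self.injected_current_A > 0:
            raise ConfigError("solver.injected_current_A must be > 0")
        if not self.tol > 0:
            raise ConfigError("solver.tol must be > 0")


@dataclass(frozen=True)
class ProtocolSettings:
    """Which experiment driver to run, and its parameters."""

    name: str = "insertion_depth_profile"
    axis: str = "x"
    n_x: int = 12
    n_y: int = 12
    recorded_contacts: Optional[Tuple[str, ...]] = None
    layer: str = "scala_tympani"
    step: float = 0.05
    range_: float = 0.10
    contact: str = "E16"
    placement_offsets: Tuple[float, float] = (0.0, 0.0)

    _NAMES = (
        "insertion_depth_profile",
        "sequential_insertion",
        "proximity_sweep",
        "conductivity_sensitivity",
        "validate",
    )

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ConfigError(
                f"protocol.name must be one of {self._NAMES}, got {self.name!r}"
            )
        if self.axis not in ("x", "y"):
            raise ConfigError("protocol.axis must be 'x' or 'y'")


@dataclass(frozen=True)
class Seeds:
    """Seeds recorded in result sidecars (the pipeline is deterministic)."""

    mesher_seed: int = 0
    protocol_seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    geometry: CochleaParams = field(default_factory=CochleaParams)
    array: ElectrodeArraySpec = field(default_factory=ElectrodeArraySpec)
    conductivity: ConductivityTable = field(default_factory=ConductivityTable)
    mesh: MeshOptions = field(default_factory=MeshOptions.coarse)
    solver: SolverSettings = field(default_factory=SolverSettings)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)
    output_dir: str = "results"
    seeds: Seeds = field(default_factory=Seeds)


# key aliases accepted in config files (file key -> dataclass field)
_ALIASES: Dict[type, Dict[str, str]] = {ProtocolSettings: {"range": "range_"}}
_SECTION_TYPES: Dict[str, type] = {
    "geometry": CochleaParams,
    "array": ElectrodeArraySpec,
    "mesh": MeshOptions,
    "solver": SolverSettings,
    "protocol": ProtocolSettings,
    "seeds": Seeds,
}


def _coerce(value, default):
    """Lists in YAML/JSON stand in for tuple-typed fields.

    PyYAML reads dot-less scientific notation such as ``6e-4`` as a string;
    coerce strings back to numbers for numeric fields.
    """
    if isinstance(default, tuple) and isinstance(value, list):
        return tuple(_coerce(v, default[0] if default else 0.0) for v in value)
    if isinstance(default, float) and isinstance(value, str):
        return float(value)
    if isinstance(default, bool):
        return value
    if isinstance(default, int) and isinstance(value, str):
        return int(value)
    if isinstance(default, float) and isinstance(value, int):
        return float(value)
    return value


def _build_section(cls: type, data, path: str):
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    # section defaults match the defaults used when the section is absent
    defaults = MeshOptions.coarse() if cls is MeshOptions else cls()
    aliases = _ALIASES.get(cls, {})
    kwargs = {}
    for key, value in data.items():
        name = aliases.get(key, key)
        if name not in fields:
            raise ConfigError(f"unknown key '{path}.{key}'")
        kwargs[name] = _coerce(value, getattr(defaults, name))
    try:
        return dataclasses.replace(defaults, **kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError, NotImplementedError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_conductivity(data, path: str) -> ConductivityTable:
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping")
    sigma = dict(DEFAULT_SIGMA_S_PER_M)
    thickness = DEFAULT_STRIA_THICKNESS_M
    for key, value in data.items():
        if key == "stria_thickness_m":
            thickness = float(value)
        elif key == "sigma_S_per_m":
            if not isinstance(value, Mapping):
                raise ConfigError(f"{path}.sigma_S_per_m: expected a mapping")
            unknown = sorted(set(value) - set(sigma))
            if unknown:
                raise ConfigError(
                    f"unknown tissue in '{path}.sigma_S_per_m': {unknown}"
                )
            sigma.update({k: float(v) for k, v in value.items()})
        else:
            raise ConfigError(f"unknown key '{path}.{key}'")
    try:
        return ConductivityTable(sigma_S_per_m=sigma, stria_thickness_m=thickness)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _read_mapping(path: Union[str, Path]) -> Mapping:
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{p}: top level must be a mapping")
    return data


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields pure defaults.  Unknown keys anywhere in the tree
    raise :class:`ConfigError` naming the offending key; non-positive
    conductivities and other invalid values are rejected with the section
    path in the message.
    """
    data = _read_mapping(path)
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "conductivity":
            kwargs[key] = _build_conductivity(value, key)
        elif key == "output_dir":
            if not isinstance(value, str):
                raise ConfigError("output_dir must be a string")
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown key '{key}'")
    return RunConfig(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        aliases = {v: k for k, v in _ALIASES.get(type(obj), {}).items()}
        for f in dataclasses.fields(obj):
            out[aliases.get(f.name, f.name)] = _to_plain(getattr(obj, f.name))
        return out
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> Dict:
    """Plain-data representation of a config (as written by dump_config)."""
    return _to_plain(config)


def dump_config(config: RunConfig, path: Union[str, Path]) -> Path:
    """Write a config as YAML (or JSON for a .json path); round-trips exactly."""
    p = Path(path)
    data = config_to_dict(config)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=True))
    return p


def run_config_hash(config: RunConfig) -> str:
    """Stable hash of the full run configuration."""
    return config_hash(config_to_dict(config))
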