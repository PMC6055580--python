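"""Structured configuration for the full pipeline.

A single YAML file describes the column geometry, the gradient magnitudes,
the per-age vital-rate parameters, the simulation grid, the generator
settings and the analysis options.  Unknown keys and unit violations are
rejected with errors naming the offending field; every run must carry an
explicit root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .column import TREATMENTS, build_column
from .ibm import AgeClassParams, ModelParams, default_params
from .rates import GrowthParams, PerceptionParams, RDParams

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised for invalid or incomplete configuration files."""


@dataclass(frozen=True)
class ColumnSettings:
    n_sectors: int = 10
    total_depth_m: float = 1.0
    sector_volume_L: float = 0.6


@dataclass(frozen=True)
class GradientSettings:
    food_surface_mgC_L: float = 0.8
    food_attenuation_per_m: float = 3.0
    food_uniform_mgC_L: float = 0.8
    light_surface: float = 100.0
    light_attenuation_per_m: float = 4.6
    light_uniform: float = 10.0


@dataclass(frozen=True)
class SimulationGrid:
    treatments: tuple = ("none", "food", "risk", "both")
    ages: tuple = ("juvenile", "adult")
    counts: tuple = (1, 4, 15, 60, 150, 360)
    response_types: tuple = ("II", "III")
    n_steps: int = 200
    burn_in: int = 100
    n_replicates: int = 100
    initial_sector: int = 4


@dataclass(frozen=True)
class AnalysisSettings:
    family_alpha: float = 0.05
    n_experiment_comparisons: int = 12
    n_verification_comparisons: int = 4


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    column: ColumnSettings = field(default_factory=ColumnSettings)
    gradients: GradientSettings = field(default_factory=GradientSettings)
    params: ModelParams = field(default_factory=default_params)
    simulation: SimulationGrid = field(default_factory=SimulationGrid)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    counting_error: float = 0.05
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        try:
            build_column(
                self.column.n_sectors,
                self.column.total_depth_m,
                self.column.sector_volume_L,
            )
        except ValueError as exc:
            raise ConfigError(f"invalid column geometry: {exc}") from exc
        g = self.gradients
        for name in (
            "food_surface_mgC_L", "food_attenuation_per_m", "food_uniform_mgC_L",
            "light_surface", "light_attenuation_per_m", "light_uniform",
        ):
            if getattr(g, name) < 0:
                raise ConfigError(f"gradients.{name} must be >= 0")
        for tr in self.simulation.treatments:
            if tr not in TREATMENTS:
                raise ConfigError(f"simulation.treatments: unknown preset {tr!r}")
        if not 0 <= self.counting_error < 1:
            raise ConfigError("counting_error must be in [0, 1)")
        if not 0 < self.analysis.family_alpha < 1:
            raise ConfigError("analysis.family_alpha must be in (0, 1)")


_SECTION_TYPES = {
    "column": ColumnSettings,
    "gradients": GradientSettings,
    "simulation": SimulationGrid,
    "analysis": AnalysisSettings,
}

_PARAM_LEAVES = {
    "growth": GrowthParams,
    "rd": RDParams,
    "perception": PerceptionParams,
}


def _build_section(cls, mapping: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for key, val in mapping.items():
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path}: {exc}") from exc


def _build_age(mapping: dict, path: str) -> AgeClassParams:
    default = default_params()
    base = default.adult if path.endswith("adult") else default.juvenile
    leaves = {}
    for name, cls in _PARAM_LEAVES.items():
        sub = mapping.get(name, {})
        leaves[name] = replace(getattr(base, name), **sub) if sub else getattr(base, name)
    gamma = mapping.get("gamma", base.gamma)
    unknown = set(mapping) - (set(_PARAM_LEAVES) | {"gamma"})
    if unknown:
        raise ConfigError(f"unknown keys under {path}: {sorted(unknown)}")
    try:
        return AgeClassParams(
            growth=leaves["growth"], rd=leaves["rd"],
            perception=leaves["perception"], gamma=gamma,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid section {path}: {exc}") from exc


def _build_params(mapping: dict) -> ModelParams:
    default = default_params()
    known = {"juvenile", "adult", "mortality", "handling", "n_exponent"}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown keys under params: {sorted(unknown)}")
    try:
        return ModelParams(
            juvenile=_build_age(mapping.get("juvenile", {}), "params.juvenile"),
            adult=_build_age(mapping.get("adult", {}), "params.adult"),
            mortality=(
                replace(default.mortality, **mapping["mortality"])
                if mapping.get("mortality") else default.mortality
            ),
            handling=mapping.get("handling", default.handling),
            n_exponent=mapping.get("n_exponent", default.n_exponent),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid params: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline configuration file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known_top = {"seed", "params", "counting_error", "output_dir"} | set(
        _SECTION_TYPES
    )
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit seed")
    kwargs = {"seed": int(raw["seed"])}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    if "params" in raw:
        kwargs["params"] = _build_params(raw["params"] or {})
    if "counting_error" in raw:
        kwargs["counting_error"] = float(raw["counting_error"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return PipelineConfig(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    plain = _to_plain(config)
    # derived, non-settable field of the column geometry
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=False))


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a resolved configuration."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
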