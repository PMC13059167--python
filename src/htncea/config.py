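"""YAML run configuration: validated load/save with defaults.

One flat, human-readable file drives a full run. Every parameter has a
documented default (the base-case input set), unknown keys are rejected
by name, and out-of-domain values raise errors naming the offending key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .params import (
    CEASettings,
    CostInputs,
    DisabilityWeights,
    DomainError,
    ModelInputs,
    ModelSettings,
    RiskMappingParams,
    ScenarioSpec,
    TransitionParameters,
    default_scenarios,
)
from .risk import ChartParams
from .synthetic import CohortSpec


class ConfigError(ValueError):
    """Malformed, unknown, or out-of-domain configuration entry."""


@dataclass(frozen=True)
class RunPaths:
    """Optional CSV inputs; synthetic generation is used when absent."""

    cohort_csv: str | None = None
    chart_csv: str | None = None
    life_table_csv: str | None = None


@dataclass(frozen=True)
class RunFlags:
    """Pipeline stage switches."""

    calibrate: bool = True
    calibration_target: float = 7_980.0
    run_dsa: bool = False
    run_psa: bool = False
    psa_draws: int = 100
    psa_mode: str = "cohort"

    def __post_init__(self) -> None:
        if self.psa_draws < 1:
            raise DomainError("psa_draws must be >= 1")
        if self.psa_mode not in ("cohort", "hybrid"):
            raise DomainError("psa_mode must be 'cohort' or 'hybrid'")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 12345
    output_dir: str = "htncea_out"
    model: ModelSettings = field(default_factory=ModelSettings)
    risk: RiskMappingParams = field(default_factory=RiskMappingParams)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    weights: DisabilityWeights = field(default_factory=DisabilityWeights)
    costs: CostInputs = field(default_factory=CostInputs)
    cea: CEASettings = field(default_factory=CEASettings)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    chart: ChartParams = field(default_factory=ChartParams)
    scenarios: dict = field(default_factory=default_scenarios)
    paths: RunPaths = field(default_factory=RunPaths)
    flags: RunFlags = field(default_factory=RunFlags)

    def model_inputs(self) -> ModelInputs:
        return ModelInputs(
            settings=self.model,
            risk=self.risk,
            transitions=self.transitions,
            weights=self.weights,
            costs=self.costs,
            scenarios=self.scenarios,
        )


def _coerce(value):
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    return value


def _build(dc_type, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in fields(dc_type)}
    for key in data:
        if key not in valid:
            raise ConfigError(f"unknown configuration key {path}.{key}")
    try:
        return dc_type(**{k: _coerce(v) for k, v in data.items()})
    except DomainError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_BLOCKS = {
    "model": ModelSettings,
    "risk": RiskMappingParams,
    "transitions": TransitionParameters,
    "weights": DisabilityWeights,
    "costs": CostInputs,
    "cea": CEASettings,
    "cohort": CohortSpec,
    "chart": ChartParams,
    "paths": RunPaths,
    "flags": RunFlags,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for key in list(data):
        if key in ("seed", "output_dir"):
            kwargs[key] = data.pop(key)
        elif key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], data.pop(key), key)
        elif key == "scenarios":
            block = data.pop(key)
            scenarios = default_scenarios()
            if not isinstance(block, dict):
                raise ConfigError("scenarios: expected a mapping of scenario specs")
            for name, spec in block.items():
                spec = dict(spec or {})
                spec.setdefault("name", name)
                scenarios[name] = _build(ScenarioSpec, spec, f"scenarios.{name}")
            kwargs["scenarios"] = scenarios
    if data:
        raise ConfigError(f"unknown configuration key {sorted(data)[0]}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration. An empty file
    yields the documented defaults."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict:
    def undo(obj):
        if is_dataclass(obj):
            return {k: undo(v) for k, v in asdict(obj).items()}
        if isinstance(obj, tuple):
            return [undo(v) for v in obj]
        if isinstance(obj, dict):
            return {k: undo(v) for k, v in obj.items()}
        return obj

    out = {
        "seed": config.seed,
        "output_dir": config.output_dir,
        **{name: undo(getattr(config, name)) for name in _BLOCKS},
        "scenarios": {name: undo(spec) for name, spec in config.scenarios.items()},
    }
    return out


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
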