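"""Run configuration: schema, defaults per setting, YAML round-trip.

A run is described by the task setting, the plasticity-rule parameters, the
task parameters (with standard per-setting defaults), the grid parameters
and a seed.  ``load_config`` merges a YAML/JSON file and/or
keyword overrides onto the defaults and validates the result, reporting all
offending fields at once.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .action import ActionSelectionConfig
from .core import ConfigurationError, PlasticityRule, SimGrid
from .value import ValueEstimationConfig

__all__ = ["RunConfig", "load_config", "dump_config"]

_TASK_FIELDS = {
    "action": {f.name for f in dataclasses.fields(ActionSelectionConfig)},
    "value": {f.name for f in dataclasses.fields(ValueEstimationConfig)},
}
_RULE_FIELDS = {f.name for f in dataclasses.fields(PlasticityRule)}
_GRID_FIELDS = {f.name for f in dataclasses.fields(SimGrid)}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one simulation run."""

    setting: str = "action"
    rule: PlasticityRule = field(
        default_factory=lambda: PlasticityRule("additive"))
    task: object = field(default_factory=ActionSelectionConfig)
    grid: SimGrid = field(default_factory=SimGrid)
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "setting": self.setting,
            "rule": dataclasses.asdict(self.rule),
            "task": dataclasses.asdict(self.task),
            "grid": dataclasses.asdict(self.grid),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _build_section(cls, data: dict, section: str, errors: list):
    try:
        return cls(**data)
    except (ConfigurationError, TypeError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def load_config(source=None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a file path, mapping, or overrides.

    ``source`` may be a path to a YAML or JSON file, a mapping, or None.
    Keyword overrides win over the file; the task defaults are the standard
    per-setting values (action: beta = 1e6, T_del = 10 s, r_dop = 1/21 s^-1,
    lambda = 0.01; value: beta = 1, T_del = 3 s, r_dop = 1/7 s^-1,
    lambda = 0.001, lambda_bar = 0.0025).  Unknown keys and constraint
    violations raise a single error listing every offending field.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, dict):
            data = dict(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **val}
        else:
            data[key] = val

    errors: list[str] = []
    setting = data.pop("setting", "action")
    if setting not in ("action", "value"):
        errors.append(f"setting: must be 'action' or 'value', got {setting!r}")
        setting = "action"
    seed = data.pop("seed", 0)
    out_dir = data.pop("out_dir", None)

    rule_data = dict(data.pop("rule", {}))
    rule_data.setdefault("kind", "additive")
    rule_data.setdefault(
        "lambda_rate", 0.01 if setting == "action" else 0.001)
    unknown = set(rule_data) - _RULE_FIELDS
    if unknown:
        errors.append(f"rule: unknown keys {sorted(unknown)}")
        for k in unknown:
            rule_data.pop(k)
    rule = _build_section(PlasticityRule, rule_data, "rule", errors)

    task_data = dict(data.pop("task", {}))
    task_cls = (ActionSelectionConfig if setting == "action"
                else ValueEstimationConfig)
    unknown = set(task_data) - _TASK_FIELDS[setting]
    if unknown:
        errors.append(f"task: unknown keys {sorted(unknown)}")
        for k in unknown:
            task_data.pop(k)
    if "rates" in task_data:
        task_data["rates"] = tuple(task_data["rates"])
    task = _build_section(task_cls, task_data, "task", errors)

    grid_data = dict(data.pop("grid", {}))
    unknown = set(grid_data) - _GRID_FIELDS
    if unknown:
        errors.append(f"grid: unknown keys {sorted(unknown)}")
        for k in unknown:
            grid_data.pop(k)
    grid = _build_section(SimGrid, grid_data, "grid", errors)

    if data:
        errors.append(f"unknown top-level keys {sorted(data)}")
    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(setting=setting, rule=rule, task=task, grid=grid,
                     seed=int(seed), out_dir=out_dir)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize a RunConfig to YAML; round-trips through load_config."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def echo_manifest(config: RunConfig, path) -> None:
    """Write the resolved config as JSON next to a run's outputs."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
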