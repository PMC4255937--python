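"""Human-editable YAML experiment configuration.

A config file fully determines an experiment: scenarios (population, drug,
deviations, dose, endpoint), designs, replicate count and root seed.
``load_config`` -> validated :class:`ExperimentPlan`; ``dump_config`` writes
a plan back out; load -> dump -> load is the identity.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .designs import DesignSpec
from .drug_disease import DrugModelSpec
from .engine import ExperimentPlan
from .exceptions import ConfigurationError
from .execution import DeviationSpec
from .population import PopulationSpec
from .ranking import PreferenceProfile
from .scenario import ScenarioSpec

__all__ = ["load_config", "dump_config", "plan_from_dict", "plan_to_dict", "load_profile"]

_PAIR_FIELDS = {"age_dist", "baseline_dist", "progression_dist", "sensitivity_dist"}
_TUPLE_FIELDS = {"interim_schedule", "delay_arms"}


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{where}: unknown field(s) {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if key in _PAIR_FIELDS or (key in _TUPLE_FIELDS and value is not None):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc
    except TypeError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def _scenario_from_dict(data: dict, where: str) -> ScenarioSpec:
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    data = dict(data)
    sub = {}
    if "population" not in data:
        raise ConfigurationError(f"{where}: missing required field 'population'")
    if "drug" not in data:
        raise ConfigurationError(f"{where}: missing required field 'drug'")
    pop = dict(data.pop("population"))
    if "deviation_defaults" in pop:
        pop["deviation_defaults"] = _build(
            DeviationSpec, pop["deviation_defaults"], f"{where}.population.deviation_defaults"
        )
    sub["population"] = _build(PopulationSpec, pop, f"{where}.population")
    sub["drug"] = _build(DrugModelSpec, data.pop("drug"), f"{where}.drug")
    if data.get("drug_b") is not None:
        sub["drug_b"] = _build(DrugModelSpec, data.pop("drug_b"), f"{where}.drug_b")
    else:
        data.pop("drug_b", None)
    if data.get("deviations") is not None:
        sub["deviations"] = _build(DeviationSpec, data.pop("deviations"), f"{where}.deviations")
    else:
        data.pop("deviations", None)
    return _build(ScenarioSpec, {**data, **sub}, where)


def plan_from_dict(data: dict) -> ExperimentPlan:
    """Build a validated plan from a parsed config mapping."""
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    data = dict(data)
    scenarios_raw = data.pop("scenarios", None)
    designs_raw = data.pop("designs", None)
    if not scenarios_raw:
        raise ConfigurationError("config: missing required field 'scenarios'")
    if not designs_raw:
        raise ConfigurationError("config: missing required field 'designs'")
    scenarios = tuple(
        _scenario_from_dict(s, f"scenarios[{i}]") for i, s in enumerate(scenarios_raw)
    )
    designs = tuple(_build(DesignSpec, d, f"designs[{i}]") for i, d in enumerate(designs_raw))
    return _build(ExperimentPlan, {**data, "scenarios": scenarios, "designs": designs}, "config")


def _clean(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _clean(v) for k, v in dataclasses.asdict(obj).items() if v is not None}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def plan_to_dict(plan: ExperimentPlan) -> dict:
    out = _clean(plan)
    return out


def load_config(path) -> ExperimentPlan:
    """Load and validate an experiment config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: not valid YAML: {exc}") from exc
    try:
        return plan_from_dict(data)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def dump_config(plan: ExperimentPlan, path) -> None:
    """Write a plan as YAML (round-trips through :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=False)


def load_profile(path) -> PreferenceProfile:
    """Load a preference profile from a small YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PreferenceProfile, data, "profile")
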