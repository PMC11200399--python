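"""YAML (de)serialization of scenario configs, behavior names as keys."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .labels import BehaviorLabel, parse_behavior
from .simulate import SyntheticScenario


def _labels_to_names(mapping: Mapping[BehaviorLabel, Any]) -> dict[str, Any]:
    return {k.value: v for k, v in mapping.items()}


def _names_to_labels(mapping: Mapping[str, Any]) -> dict[BehaviorLabel, Any]:
    return {parse_behavior(k): v for k, v in mapping.items()}


def scenario_to_dict(scenario: SyntheticScenario) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in fields(scenario):
        value = getattr(scenario, f.name)
        if f.name in ("behavior_mix", "bout_mean_s", "detect_prob"):
            value = _labels_to_names(value)
        elif f.name == "mislabel_matrix":
            value = {
                truth.value: _labels_to_names(row) for truth, row in value.items()
            }
        elif f.name == "confidence_model":
            value = {k: list(v) for k, v in value.items()}
        elif isinstance(value, tuple):
            value = list(value)
        out[f.name] = value
    return out


def scenario_from_dict(data: Mapping[str, Any]) -> SyntheticScenario:
    known = {f.name for f in fields(SyntheticScenario)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
    kwargs: dict[str, Any] = dict(data)
    for key in ("behavior_mix", "bout_mean_s", "detect_prob"):
        if key in kwargs:
            kwargs[key] = _names_to_labels(kwargs[key])
    if "mislabel_matrix" in kwargs:
        kwargs["mislabel_matrix"] = {
            parse_behavior(t): _names_to_labels(row)
            for t, row in kwargs["mislabel_matrix"].items()
        }
    if "confidence_model" in kwargs:
        kwargs["confidence_model"] = {
            k: tuple(v) for k, v in kwargs["confidence_model"].items()
        }
    for key in ("arena", "box_size_base"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticScenario(**kwargs)


def load_scenario(path: Path | str) -> SyntheticScenario:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return scenario_from_dict(data)


def dump_scenario(scenario: SyntheticScenario, path: Path | str) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)
    return path


__all__ = ["scenario_to_dict", "scenario_from_dict", "load_scenario", "dump_scenario"]
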