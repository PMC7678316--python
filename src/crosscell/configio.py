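"""YAML/JSON configuration loading.

Config documents use exactly the dataclass field names: a generator config
is a flat mapping of :class:`~crosscell.generate.GeneratorConfig` fields; an
experiment config is a mapping of :class:`~crosscell.pipeline.ExperimentConfig`
fields with ``generator`` as a nested mapping and ``model_grid`` as a list
of mappings with :class:`~crosscell.pipeline.GridPoint` fields.  Unknown
keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .generate import ConfigError, GeneratorConfig
from .pipeline import ExperimentConfig, GridPoint

__all__ = [
    "load_config_file",
    "generator_config_from_dict",
    "experiment_config_from_dict",
]


def load_config_file(path) -> dict:
    """Parse a YAML or JSON config document into a mapping."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    return data


def _check_keys(data: dict, cls, context: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{context}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def generator_config_from_dict(data: dict) -> GeneratorConfig:
    _check_keys(data, GeneratorConfig, "generator config")
    cfg = GeneratorConfig(**data)
    cfg.validate()
    return cfg


def experiment_config_from_dict(data: dict) -> ExperimentConfig:
    data = dict(data)
    _check_keys(data, ExperimentConfig, "experiment config")
    if "generator" in data:
        data["generator"] = generator_config_from_dict(dict(data["generator"]))
    if "model_grid" in data:
        points = []
        for i, entry in enumerate(data["model_grid"]):
            entry = dict(entry)
            _check_keys(entry, GridPoint, f"model_grid[{i}]")
            if entry.get("schemes") is not None:
                entry["schemes"] = tuple(entry["schemes"])
            points.append(GridPoint(**entry))
        data["model_grid"] = points
    for key in ("schemes", "train_cell_types", "test_chromosomes"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    cfg = ExperimentConfig(**data)
    cfg.validate()
    return cfg
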