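"""Flat YAML configuration: defaults shipped with the package, user files
merged on top."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "save_config"]


def default_config() -> dict:
    """The packaged default configuration (deep copy, safe to mutate)."""
    text = (
        resources.files("epinetsim").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
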