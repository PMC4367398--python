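"""YAML configuration with validated defaults for every tunable."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import GeomParams
from .hough import PPHTParams
from .pipeline import DigitizeConfig
from .synthetic import CameraModel, NoiseModel

_SECTIONS = {
    "digitize": DigitizeConfig,
    "ppht": PPHTParams,
    "geometry": GeomParams,
    "camera": CameraModel,
    "noise": NoiseModel,
}


def default_config() -> dict:
    """Nested dict of every tunable and its default, grouped by module."""
    out = {"seed": 0}
    for name, cls in _SECTIONS.items():
        out[name] = {f.name: getattr(cls(), f.name) for f in fields(cls)
                     if f.name != "ppht"}
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML file (and/or a dict) over the defaults.

    Unknown sections or keys are rejected; scalar types must match the
    default's type family.
    """
    cfg = default_config()
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **overrides}
    for section, values in raw.items():
        if section == "seed":
            cfg["seed"] = int(values)
            continue
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for k, v in values.items():
            if k not in cfg[section]:
                raise ConfigError(f"unknown key {section}.{k}")
            ref = cfg[section][k]
            if isinstance(ref, bool) and not isinstance(v, bool):
                raise ConfigError(f"{section}.{k} must be a boolean")
            if isinstance(ref, (int, float)) and not isinstance(v, (int, float)):
                raise ConfigError(f"{section}.{k} must be numeric")
            cfg[section][k] = v
    return cfg


def digitize_config(cfg: dict) -> DigitizeConfig:
    d = dict(cfg["digitize"])
    d.pop("ppht", None)
    ppht = PPHTParams(**cfg["ppht"])
    ppht.seed = cfg.get("seed", ppht.seed)
    return DigitizeConfig(ppht=ppht, **d)


def geom_params(cfg: dict) -> GeomParams:
    gp = GeomParams(**cfg["geometry"])
    gp.seed = cfg.get("seed", gp.seed)
    return gp
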