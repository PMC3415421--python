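"""Flat YAML configuration mapped onto the simulation and grid dataclasses."""

from __future__ import annotations

import dataclasses

import yaml

from .experiment import GridSpec
from .simulate import SimulationConfig, WrightParams

__all__ = ["load_config", "simulation_config_from_dict", "grid_spec_from_dict"]


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return cfg


def _pick(cfg: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for key, val in cfg.items():
        if key in names:
            out[key] = tuple(val) if isinstance(val, list) else val
    return out


def simulation_config_from_dict(cfg: dict) -> SimulationConfig:
    kwargs = _pick(cfg, SimulationConfig)
    wright_kwargs = _pick(cfg, WrightParams)
    # avoid WrightParams fields leaking into SimulationConfig (no overlap today)
    if wright_kwargs:
        kwargs["wright"] = WrightParams(**wright_kwargs)
    return SimulationConfig(**kwargs)


def grid_spec_from_dict(cfg: dict) -> GridSpec:
    return GridSpec(**_pick(cfg, GridSpec))
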