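"""Flat TOML configuration mapping onto the pipeline parameters.

Keys mirror the dataclass field names, e.g.::

    threshold = 90
    gaussian_sigma = 1.5
    n_grid = 8
    alpha = 0.15
"""

from __future__ import annotations

import tomllib
from dataclasses import fields, replace
from pathlib import Path

from .pipeline import AnalysisConfig
from .preprocess import PreprocessParams

__all__ = ["load_config", "apply_overrides"]

_PRE_FIELDS = {f.name for f in fields(PreprocessParams)}
_CFG_FIELDS = {f.name for f in fields(AnalysisConfig)} - {"preprocess"}


def apply_overrides(config: AnalysisConfig, overrides: dict) -> AnalysisConfig:
    """Return a config with the given flat key overrides applied.

    Keys are routed to PreprocessParams or AnalysisConfig by name;
    unknown keys raise.
    """
    pre_kv = {}
    cfg_kv = {}
    for key, value in overrides.items():
        if value is None:
            continue
        if key in _PRE_FIELDS:
            if key in ("gray_weights", "stretch_percentiles"):
                value = tuple(value)
            pre_kv[key] = value
        elif key in _CFG_FIELDS:
            cfg_kv[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    if pre_kv:
        cfg_kv["preprocess"] = replace(config.preprocess, **pre_kv)
    return replace(config, **cfg_kv) if cfg_kv else config


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a flat TOML file into an AnalysisConfig (defaults if None)."""
    config = AnalysisConfig()
    if path is None:
        return config
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return apply_overrides(config, data)
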