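"""Pipeline configuration: one YAML document with per-stage namespaces.

Unknown keys are rejected before any computation; all defaults are
materialized so the resolved configuration written to the run log is
complete and re-runnable.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "dump_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "spotgrid_out",
    "grid": {
        "p_low": 1.0,
        "p_high": 99.0,
        "method": "otsu",
        "percentile_q": 90.0,
        "open_radius": 1,
        "area_band": [0.3, 3.0],
        "expected_shape": None,
    },
    "segmentation": {
        "h": 1.0,
        "min_seed_distance": 3.0,
    },
    "viability": {
        "max_match_distance": None,
    },
    "colorimetric": {
        "transform": "luminance",
        "channel": "R",
        "weights": [1.0, 0.0, 0.0],
        "aggregator": "median",
    },
    "simulate": {
        "rows": 4,
        "cols": 6,
        "pitch_x": 40.0,
        "pitch_y": 40.0,
        "rotation_deg": 0.0,
        "spot_radius": 12.0,
        "background_level": 0.1,
        "spot_level": 0.9,
        "noise_sigma": 0.0,
        "cells_per_spot": 3,
        "alive_fraction": 0.75,
        "faint_calcein_prob": 0.0,
        "cell_radius_range": [2.5, 3.5],
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def resolve_config(override: dict | None = None) -> dict:
    """Merge an override onto the defaults, rejecting unknown keys."""
    return _merge(DEFAULT_CONFIG, override or {})


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file and resolve it against the defaults."""
    if path is None:
        return resolve_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return resolve_config(data)


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
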