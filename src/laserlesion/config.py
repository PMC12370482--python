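"""Pipeline configuration: YAML loading with schema validation.

The shipped ``defaults.yaml`` records every paper-gap default in one place;
user configs are validated against the same schema (unknown keys and type
mismatches are rejected before any stage runs).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .errors import SchemaError

__all__ = ["load_defaults", "load_config", "validate_config"]

# section -> key -> allowed types (None allows YAML null)
_SCHEMA: dict[str, dict[str, tuple]] = {
    "seed": {"__scalar__": (int,)},
    "rats_schedule": {
        "min_leaf": (list,),
        "lambda_factor": (int, float),
        "noise_sd": (int, float, type(None)),
        "significance": (int, float),
    },
    "masking": {
        "saturated_fraction": (int, float),
        "clean_iterations": (int,),
    },
    "orientation": {
        "flip_rows": (bool,),
        "flip_cols": (bool,),
        "rot90": (int,),
    },
    "alignment": {
        "roi": (str,),
        "steady_state_fraction": (int, float),
    },
    "scoring": {
        "min_dead_cells": (int,),
        "central_radius_fraction": (int, float),
        "min_circularity": (int, float),
        "footprint_tolerance": (int, float),
        "red_mad_factor": (int, float),
    },
    "analysis": {
        "reciprocity_tolerance": (int, float),
        "dose_uncertainty": (int, float),
        "fiducial_level": (int, float),
        "slope_gate": (int, float),
        "fiducial_rel_limit": (int, float),
    },
    "simulation": {
        "ambient_C": (int, float),
        "rise_time_constant_s": (int, float),
        "diffusion_sigma_um": (int, float),
        "camera_noise_sd_C": (int, float),
        "cell_density_mm2": (int, float),
        "nucleus_radius_um": (int, float),
        "bleedthrough_coeff": (int, float),
        "halo_intensity_factor": (int, float),
        "halo_radius_factor": (int, float),
    },
}


def validate_config(cfg: dict) -> dict:
    """Validate a config mapping against the schema; returns it unchanged."""
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    for section, value in cfg.items():
        if section not in _SCHEMA:
            raise SchemaError(f"unknown config section '{section}'")
        spec = _SCHEMA[section]
        if "__scalar__" in spec:
            if not isinstance(value, spec["__scalar__"]):
                raise SchemaError(
                    f"'{section}' must be {spec['__scalar__']}, got {value!r}"
                )
            continue
        if not isinstance(value, dict):
            raise SchemaError(f"section '{section}' must be a mapping")
        for key, v in value.items():
            if key not in spec:
                raise SchemaError(f"unknown key '{section}.{key}'")
            if not isinstance(v, spec[key]) or (
                isinstance(v, bool) and bool not in spec[key]
            ):
                raise SchemaError(
                    f"'{section}.{key}' has wrong type: {v!r}"
                )
    return cfg


def load_defaults() -> dict:
    text = resources.files("laserlesion").joinpath("defaults.yaml").read_text()
    return validate_config(yaml.safe_load(text))


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with an optional user YAML (validated)."""
    cfg = load_defaults()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    validate_config(user)
    merged = copy.deepcopy(cfg)
    for section, value in user.items():
        if isinstance(value, dict):
            merged.setdefault(section, {}).update(value)
        else:
            merged[section] = value
    return validate_config(merged)
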