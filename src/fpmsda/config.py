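"""Experiment configuration: schema, defaults, loading and validation.

A configuration is a YAML or JSON document with sections ``geometry``,
``object``, ``simulation``, ``noise``, ``correction``, ``reconstruction``
and ``evaluation``.  Unknown keys and type violations are collected and
reported together in a single schema error.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import yaml

from .datatypes import ComplexObject
from .fixtures import make_bar_target, make_texture_object
from .forward import NoiseModel
from .geometry import IlluminationGeometry, led_grid


class ConfigSchemaError(ValueError):
    """Invalid experiment configuration; message lists offending keys."""


_NUM = (int, float)

#: section -> key -> (allowed types, default); default None means required
SCHEMA: dict[str, dict[str, tuple]] = {
    "geometry": {
        "grid": ((int,), 15),
        "pitch_mm": (_NUM, 5.0),
        "height_mm": (_NUM, 60.0),
        "wavelength_nm": (_NUM, 532.0),
        "objective_na": (_NUM, 0.16),
        "hybrid_band": (_NUM, 0.02),
        "max_radius_mm": (_NUM + (type(None),), 35.0),
    },
    "object": {
        "kind": ((str,), "bars"),
        "shape": ((int,), 288),
        "pixel_size_um": (_NUM, 0.27),
        "seed": ((int,), 1),
        "bar_periods": ((list,), [16, 10, 6]),
        "bar_amplitude": (_NUM, 0.2),
        "fill_fraction": (_NUM, 0.4),
    },
    "simulation": {
        "lr_shape": ((int,), 96),
        "intensity_scale": (_NUM, 50000.0),
    },
    "noise": {
        "offset": (_NUM, 300.0),
        "gaussian_sigmas": ((list,), [0.0, 500.0, 1000.0, 1500.0]),
        "poisson_gain": (_NUM, 1.0),
        "seeds": ((list,), [1, 2, 3]),
    },
    "correction": {
        "methods": ((list,), ["mean", "mean3sigma", "sda"]),
        "s1_radius": ((int,), 10),
        "s2_radius": ((int,), 4),
        "rolling_ball_radius": ((int,), 8),
    },
    "reconstruction": {
        "n_iterations": ((int,), 10),
        "step_size": (_NUM, 1.0),
        "regularizer": (_NUM, 1e-3),
    },
    "evaluation": {
        "crop_margin": ((int,), 60),
    },
}

VALID_METHODS = ("mean", "mean3sigma", "rollingball", "sda")


def default_config() -> dict:
    return {
        section: {k: copy.deepcopy(v[1]) for k, v in keys.items()}
        for section, keys in SCHEMA.items()
    }


def validate_config(raw: dict) -> dict:
    """Merge a raw mapping onto the defaults, collecting schema violations."""
    if not isinstance(raw, dict):
        raise ConfigSchemaError("configuration root must be a mapping")
    errors: list[str] = []
    cfg = default_config()
    for section, content in raw.items():
        if section not in SCHEMA:
            errors.append(f"unknown section {section!r}")
            continue
        if not isinstance(content, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, value in content.items():
            if key not in SCHEMA[section]:
                errors.append(f"unknown key {section}.{key}")
                continue
            types = SCHEMA[section][key][0]
            if isinstance(value, bool) or not isinstance(value, types):
                errors.append(
                    f"{section}.{key}: expected {'/'.join(t.__name__ for t in types)}, "
                    f"got {type(value).__name__}"
                )
                continue
            cfg[section][key] = value
    for m in cfg["correction"]["methods"]:
        if m not in VALID_METHODS:
            errors.append(f"correction.methods: unknown method {m!r}")
    if errors:
        raise ConfigSchemaError("invalid configuration: " + "; ".join(errors))
    return cfg


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return validate_config(raw or {})


def geometry_from_config(cfg: dict) -> IlluminationGeometry:
    g = cfg["geometry"]
    return led_grid(
        n_side=g["grid"],
        pitch=g["pitch_mm"],
        array_height=g["height_mm"],
        wavelength=g["wavelength_nm"],
        objective_na=g["objective_na"],
        hybrid_band=g["hybrid_band"],
        max_radius=g["max_radius_mm"],
    )


def object_from_config(cfg: dict) -> ComplexObject:
    o = cfg["object"]
    if o["kind"] == "bars":
        return make_bar_target(
            o["shape"],
            list(o["bar_periods"]),
            o["pixel_size_um"],
            o["bar_amplitude"],
            o["fill_fraction"],
        )
    if o["kind"] == "texture":
        return make_texture_object(o["shape"], o["seed"], o["pixel_size_um"])
    raise ConfigSchemaError(f"object.kind: unknown kind {o['kind']!r}")


def noise_from_config(cfg: dict, sigma: float, seed: int) -> NoiseModel:
    n = cfg["noise"]
    return NoiseModel(
        offset=n["offset"],
        gaussian_sigma=sigma,
        poisson_gain=n["poisson_gain"],
        seed=seed,
    )
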