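"""Run configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "circsc_out",
    "inputs": {
        # empty paths mean "simulate instead of loading"
        "genes_mtx": "",
        "circ_mtx": "",
        "annotations": "",
        "bulk": "",
    },
    "stages": {
        "qc": True,
        "quantify": True,
        "specificity": True,
        "dynamics": True,
        "deconv": True,
    },
    "simulate": {
        "n_cells": 2000,
        "n_genes": 1000,
        "n_circ": 1000,
        "mean_bsj": 0.5,
        "embryo_features": 1000,
        "embryo_noise_sd": 0.5,
        "mixtures": 30,
        "mixture_noise_sd": 0.05,
    },
    "qc": {"nmads": 3.0, "tails": "both", "log": True},
    "quantify": {"min_total": 2, "high_conf_total": 5, "cpm_denominator": "auto"},
    "specificity": {"general_fraction": 0.5},
    "markers": {"min_fold": 3.0, "alpha": 0.05, "epsilon": 0.01},
    "dynamics": {"c": 5, "m": 1.25, "tol": 1e-6, "seed": 0, "min_stages": 2},
    "deconv": {"method": "nnls", "min_types_detected": 2, "min_fold": 3.0},
}


def _merge(defaults: Mapping[str, Any], given: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in given.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge defaults <- YAML file <- overrides, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        merged = _merge(merged, raw)
    if overrides:
        merged = _merge(merged, overrides)
    return merged
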