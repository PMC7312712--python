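"""Run configuration: one flat JSON/YAML file covering model, cohort,
analysis and output settings, with the reference study values as
defaults so a bare run reproduces the published sweep."""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from . import cone_model
from .synthetic_cohort import AgeParams, CohortConfig

__all__ = ["default_config", "load_config", "build_calibration", "build_cohort_config"]


def default_config() -> Dict[str, Any]:
    """The full default configuration tree (all reference values)."""
    d = cone_model.DEFAULTS
    return {
        "model": {
            "alpha0_deg": d["alpha0_deg"],
            "r1_0": d["r1_0"],
            "cos_decimals": d["cos_decimals"],
            "b_decimals": d["b_decimals"],
            "A1": d["A1"],
            "A2": d["A2"],
            "r2": d["r2"],
            "L": d["L"],
            "pi_volume": d["pi_volume"],
            "alpha_start": d["alpha_start"],
            "alpha_end": d["alpha_end"],
            "step": d["step"],
        },
        "cohort": {
            "n": 91,
            "male_fraction": 51.0 / 91.0,
            "angle_mean": 122.55,
            "angle_sd": 8.20,
            "angle_min": 97.20,
            "angle_max": 139.31,
            "measurement_sd": 0.5,
            "age_params": {
                "male": {"loc": 10.0, "shape": 2.0, "scale": 12.5},
                "female": {"loc": 10.0, "shape": 2.6, "scale": 11.5},
            },
            "seed": 0,
        },
        "analysis": {"alpha_level": 0.05},
        "output": {"display_decimals": 3},
    }


def _deep_merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    """Load a JSON or YAML config file merged over the defaults.

    With ``path=None`` the defaults are returned unchanged.  The format
    is inferred from the suffix (.json vs .yml/.yaml; YAML is a JSON
    superset, so unknown suffixes fall back to the YAML parser).
    """
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if user is None:
        return cfg
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(cfg, user)


def build_calibration(config: Dict[str, Any]) -> cone_model.Calibration:
    m = config["model"]
    return cone_model.calibrate_b(
        r1_0=m["r1_0"],
        alpha0_deg=m["alpha0_deg"],
        cos_decimals=m["cos_decimals"],
        b_decimals=m["b_decimals"],
    )


def build_cohort_config(config: Dict[str, Any], seed: Optional[int] = None) -> CohortConfig:
    c = dict(config["cohort"])
    if seed is not None:
        c["seed"] = seed
    c["age_params"] = {
        sex: AgeParams(**params) for sex, params in c["age_params"].items()
    }
    return CohortConfig(**c)
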