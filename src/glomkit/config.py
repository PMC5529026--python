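"""Run configuration: defaults, file round-trip, stable hashing.

Every stage parameter carries a default equal to the conventional value
where one exists (stereology coefficients K=1.1/β=1.45 and β=1.38/K=1.01;
the DEG rule FC > 2, mean RPKM > 0.5, BH < 0.05; ages 12-41 weeks with 5
animals per cohort).  Configs round-trip losslessly through YAML/JSON.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "save_config", "config_hash"]


def default_config() -> dict:
    return {
        "seed": 0,
        "simulate": {
            "n_per_cohort": 5,
            "gloms_per_animal": 44,
            "radius_glom_um": 60.0,
            "radius_glom_log_sd": 0.08,
            "n_pod_mean": 200,
            "radius_nuc_um": 3.0,
            "min_rel_area": 0.0,
            "n_genes": 4000,
            "colIV_base_frac": 0.05,
            "colIV_sev_slope": 0.06,
            "pas_base_frac": 0.08,
            "pas_sev_slope": 0.02,
            "stain_frac_noise_sd": 0.01,
        },
        "stereology": {
            "k_nuc": 1.1,
            "beta_nuc": 1.45,
            "beta_glom": 1.38,
            "k_glom": 1.01,
        },
        "morphometry": {
            "quadrat_size_um": 500.0,
        },
        "degs": {
            "fc_thresh": 2.0,
            "rpkm_thresh": 0.5,
            "alpha": 0.05,
            "pseudocount": 0.25,
            "sustained_fc": 3.0,
            "mono_tol": 0.1,
        },
        "endpoints": {
            "alpha": 0.05,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise KeyError(f"unknown config parameter: {where}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config parameter {where} must be a mapping")
            out[key] = _merge(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML/JSON override file."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(cfg, override)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
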