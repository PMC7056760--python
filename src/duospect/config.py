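"""Run configuration: TOML/YAML loading and provenance hashing."""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .io import config_hash

DEFAULTS: dict = {
    "phantom": {"name": "nema_iq", "voxel_mm": 2.0},
    "physics": {"fwhm_ref": 0.095, "e_ref_kev": 140.0,
                "ho_continuum": True},
    "geometry": {"n_angles": 120, "radius_cm": 25.0, "nu": 64, "nv": 48,
                 "pitch_cm": 0.48, "time_per_angle_s": 10.0},
    "montecarlo": {"n_histories": 20000, "seed": 1, "poisson": False},
    "recon": {"n_iterations": 20, "n_subsets": 8, "k_factor": 0.93,
              "width_correction": False},
}


def load_config(path) -> dict:
    """Load a TOML or YAML run config, merged over the defaults."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        user = yaml.safe_load(path.read_text()) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    cfg["hash"] = config_hash(cfg)
    return cfg
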