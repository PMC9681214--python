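"""YAML configuration with defaults for the pipeline CLI."""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict = {
    "parcellation_size": 200,
    "min_species": 5,
    "seed": 0,
    "n_iter": 10000,
    "n_null": 1000,
    "n_louvain_runs": 250,
    "gamma_res": 1.0,
    "rich_club_alpha": 0.05,
    "smooth_sigma": 0.015,
    "smooth_step": 0.001,
    "standardize_features": True,
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config file (if given) over the defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
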