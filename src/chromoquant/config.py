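"""YAML configuration handling for the pipeline.

A run is driven by one YAML file with sections ``image``, ``segmentation``,
``foci``, ``gfp``, ``fish``, ``bins``, ``compare`` and ``simulate``; any
omitted key falls back to the package default, and a ``per_image`` section
may override values for individual images (the reproducible stand-in for
thresholds that would otherwise be set by hand per image).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "image": {
        "channel_roles": {"dapi": 0, "mark": 1},
        "axis_order": "CZYX",
        "voxel_z_um": 0.13,
        "pixel_xy_um": 1.0,
        "z_start": 0,
        "z_count": None,  # None -> 12 sections when available, else full stack
    },
    "segmentation": {
        "smooth_radius_px": 3,
        "h": None,
        "fg_threshold": "auto",
        "min_nucleus_area_px": 30,
        "exclude_border": True,
    },
    "foci": {
        "focus_h": None,
        "focus_threshold": "auto",
        "min_focus_area_px": 2,
    },
    "gfp": {
        "threshold": None,  # None -> no compartment gating
    },
    "fish": None,  # dict like foci -> enables the FISH stage
    "bins": {
        "edges": "tertiles",  # or [e1, e2]
        "metric": "focus_intensity",
    },
    "compare": {
        "equal_var": False,
    },
    "simulate": None,  # dict of SimConfig overrides + optional conditions list
    "per_image": {},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the package defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return _deep_merge(cfg, user)


def config_for_image(cfg: dict[str, Any], image_id: str) -> dict[str, Any]:
    """Apply any ``per_image`` override section for *image_id*."""
    override = (cfg.get("per_image") or {}).get(image_id)
    if not override:
        return cfg
    return _deep_merge(cfg, {k: v for k, v in override.items() if k != "per_image"})


def demo_config_path() -> Path:
    """Path of the packaged demo configuration (two simulated conditions)."""
    return Path(__file__).parent / "data" / "demo_config.yaml"
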