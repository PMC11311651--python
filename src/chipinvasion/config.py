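"""Run configuration: a nested YAML file with CLI overrides.

Sections: ``seed``, ``geometry``, ``calibration``, ``segmentation``,
``simulation`` (arm definitions), ``stats``, ``output``.  Every section is
optional; missing values fall back to package defaults.  The SHA-256
digest of the resolved config is embedded in all outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .geometry import Calibration, ChipGeometry, build_geometry
from .simulate import default_experiment_config

__all__ = ["load_config", "config_digest", "geometry_from_config", "calibration_from_config"]


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run config; ``None`` yields the default simulation design."""
    if path is None:
        cfg: dict = {"simulation": default_experiment_config()}
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        with open(p) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    cfg.setdefault("simulation", default_experiment_config())
    cfg.setdefault("geometry", {})
    cfg.setdefault("calibration", {})
    cfg.setdefault("segmentation", {})
    cfg.setdefault("stats", {})
    if "seed" in cfg:
        cfg["simulation"]["seed"] = int(cfg["seed"])
    return cfg


def config_digest(cfg: dict) -> str:
    """Short stable digest of a resolved config, for provenance lines."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def geometry_from_config(cfg: dict) -> ChipGeometry:
    return build_geometry(**cfg.get("geometry", {}))


def calibration_from_config(cfg: dict) -> Calibration:
    cal_cfg = dict(cfg.get("calibration", {}))
    if not cal_cfg:
        cal_cfg = {"um_per_px": 1.0}
    if "origin_px" in cal_cfg:
        cal_cfg["origin_px"] = tuple(cal_cfg["origin_px"])
    return Calibration(**cal_cfg)
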