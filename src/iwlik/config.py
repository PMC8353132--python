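"""Structured configuration files and reproducibility manifests.

Config files are YAML.  An empty file (or absent keys) yields the
standard study settings: lengths {10, 30, 60}, mixes {2, 1, 0.5}, 1000
replications, and the 17-point initial-ability grid from -4 to 4 in
steps of 0.5.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .estimators import OptimizerConfig
from .simulation import StudyDesign, study1_design, study2_design

__all__ = ["ConfigError", "parse_config", "write_config", "make_manifest", "write_manifest"]

_DESIGN_KEYS = {
    "regime", "test_lengths", "mixes", "theta1_grid", "theta2_levels",
    "n_replications", "seed", "b_mean", "b_sd", "step_means", "step_sd",
    "discrimination", "disc_range",
}
_OPT_KEYS = {"tolerance", "max_iter", "bounds", "map_bounds", "damping", "grid_step"}
_TOP_KEYS = {"study"} | _DESIGN_KEYS | {"optimizer"}


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def _tupled(value):
    return tuple(value) if isinstance(value, list) else value


def parse_config(path) -> Tuple[StudyDesign, OptimizerConfig]:
    """Parse a YAML config into a study design and optimizer settings,
    filling every absent key with its standard default."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    study = raw.get("study", 1)
    if study not in (1, 2):
        raise ConfigError("study must be 1 or 2")
    overrides = {
        k: _tupled(v) for k, v in raw.items() if k in _DESIGN_KEYS
    }
    try:
        design = (study1_design if study == 1 else study2_design)(**overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    opt_raw = raw.get("optimizer", {}) or {}
    unknown = set(opt_raw) - _OPT_KEYS
    if unknown:
        raise ConfigError(f"unknown optimizer key(s): {sorted(unknown)}")
    try:
        opt = OptimizerConfig(**{k: _tupled(v) for k, v in opt_raw.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return design, opt


def write_config(design: StudyDesign, opt: OptimizerConfig, path) -> None:
    """Serialise settings so that ``parse_config(write_config(...))``
    round-trips."""
    data = {k: _listed(v) for k, v in asdict(design).items()}
    data["study"] = 1 if design.regime == "longitudinal" else 2
    data.pop("regime")
    opt_d = asdict(opt)
    opt_d.pop("init", None)
    data["optimizer"] = {k: _listed(v) for k, v in opt_d.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _listed(value):
    if isinstance(value, tuple):
        return [v.item() if hasattr(v, "item") else v for v in value]
    return value.item() if hasattr(value, "item") else value


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_manifest(
    command: str,
    design: Optional[StudyDesign],
    opt: Optional[OptimizerConfig],
    master_seed: Optional[int],
    child_seeds: Optional[dict],
    outputs,
) -> dict:
    """Reproducibility manifest: tool version, full config echo, seeds and
    output digests; everything but the timestamp is deterministic."""
    from . import __version__

    cfg = {}
    if design is not None:
        cfg["design"] = {k: _listed(v) for k, v in asdict(design).items()}
    if opt is not None:
        o = asdict(opt)
        o.pop("init", None)
        cfg["optimizer"] = {k: _listed(v) for k, v in o.items()}
    return {
        "tool": "iwlik",
        "version": __version__,
        "command": command,
        "config": cfg,
        "master_seed": master_seed,
        "child_seeds": child_seeds,
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
        "created": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
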