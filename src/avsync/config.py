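"""Run configuration: one YAML/JSON document drives every CLI command.

A run is reproducible from its config plus seed alone; every output file
carries the config hash, seed and package version in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import NetworkParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


_MODEL_KEYS = {"omega1", "omega2", "omega3", "kappa1", "kappa2", "tau", "lag_sign"}

DEFAULTS = {
    "integration": {"horizon": 200.0, "step": None, "tail_fraction": 0.25},
    "sweep": {
        "kappas": [5.0],
        "tau_max": 1.5,
        "tau_step": 0.01,
        "n_ic": 24,
        "lag_signs": ["visual_leads", "auditory_leads"],
    },
    "multistability": {"taus": [0.9], "n_ic": 24, "cluster_radius": 0.02},
    "behavior": {
        "n_subjects": 34,
        "per_lag_trials": 40,
        "peak_p_ta": 0.85,
        "width_ms": 220.0,
        "skew": 1.6,
        "p_other": 0.10,
    },
}


@dataclass
class RunConfig:
    """Validated configuration for simulations, sweeps and behavior demos."""

    model: NetworkParams
    integration: dict = field(default_factory=lambda: dict(DEFAULTS["integration"]))
    sweep: dict = field(default_factory=lambda: dict(DEFAULTS["sweep"]))
    multistability: dict = field(default_factory=lambda: dict(DEFAULTS["multistability"]))
    behavior: dict = field(default_factory=lambda: dict(DEFAULTS["behavior"]))
    seed: int = 0
    initial_phases: Optional[list] = None

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "integration": self.integration,
            "sweep": self.sweep,
            "multistability": self.multistability,
            "behavior": self.behavior,
            "seed": self.seed,
            "initial_phases": self.initial_phases,
        }

    def sidecar(self) -> dict:
        from . import __version__

        d = self.to_dict()
        d["config_hash"] = self.config_hash
        d["version"] = __version__
        return d


def _merged_section(raw: dict, name: str) -> dict:
    sec = dict(DEFAULTS[name])
    extra = raw.get(name, {}) or {}
    if not isinstance(extra, dict):
        raise ConfigError(f"section '{name}' must be a mapping, got {type(extra).__name__}")
    unknown = set(extra) - set(sec)
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    sec.update(extra)
    return sec


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "model" not in raw:
        raise ConfigError(f"{path}: missing required section 'model'")
    mdl = raw["model"]
    unknown = set(mdl) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown model keys {sorted(unknown)}")
    missing = _MODEL_KEYS - {"lag_sign"} - set(mdl)
    if missing:
        raise ConfigError(f"{path}: model section missing keys {sorted(missing)}")
    try:
        params = NetworkParams(**mdl)
    except ValueError as e:
        raise ConfigError(f"{path}: invalid model parameters: {e}") from e
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"{path}: seed must be an integer, got {seed!r}")
    ip = raw.get("initial_phases")
    if ip is not None and (not isinstance(ip, list) or len(ip) != 3):
        raise ConfigError(f"{path}: initial_phases must be a list of 3 numbers")
    return RunConfig(
        model=params,
        integration=_merged_section(raw, "integration"),
        sweep=_merged_section(raw, "sweep"),
        multistability=_merged_section(raw, "multistability"),
        behavior=_merged_section(raw, "behavior"),
        seed=seed,
        initial_phases=ip,
    )
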