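"""Run configuration: YAML loading, validation, and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the offending key path on schema violations."""


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    out_dir: str
    seed: int
    design_scale: float = 0.6
    suv_times_minutes: tuple[float, ...] = (1.25, 13.5, 50.0)
    k1_fit_window_minutes: tuple[float, float] = (0.0, 50.0)
    standardization_grouping: str = "tracer"
    harmonization_covariates: tuple[str, ...] = ("batch", "sex", "genotype", "age", "dw")
    cv_folds: int = 10
    cv_repeats: int = 10
    n_bootstrap: int = 1000
    l1_lambda_grid_size: int = 15
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["suv_times_minutes"] = list(self.suv_times_minutes)
        d["k1_fit_window_minutes"] = list(self.k1_fit_window_minutes)
        d["harmonization_covariates"] = list(self.harmonization_covariates)
        return d


_SCHEMA: dict[str, type | tuple] = {
    "out_dir": str,
    "seed": int,
    "design_scale": (int, float),
    "suv_times_minutes": list,
    "k1_fit_window_minutes": list,
    "standardization_grouping": str,
    "harmonization_covariates": list,
    "cv_folds": int,
    "cv_repeats": int,
    "n_bootstrap": int,
    "l1_lambda_grid_size": int,
    "verbosity": str,
}

_REQUIRED = ("out_dir", "seed")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; errors name the key path."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in _REQUIRED:
        if key not in raw:
            raise ConfigError(f"missing required config key: {key!r}")
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key: {key!r}")
        expected = _SCHEMA[key]
        if not isinstance(value, expected):
            raise ConfigError(
                f"config key {key!r}: expected {expected}, got {type(value).__name__}"
            )
    if raw["seed"] is None:
        raise ConfigError("config key 'seed': a seed is mandatory")
    cfg = RunConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    })
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form (for report provenance)."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
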