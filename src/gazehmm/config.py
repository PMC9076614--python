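"""Configuration loading and logging setup."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from .types import ConfigurationError

__all__ = ["load_config", "merge_config", "setup_logging", "DEFAULT_CONFIG"]

#: Pipeline defaults; any subset may be overridden from a YAML/JSON file.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_explorative": 20,
        "n_focused": 20,
        "n_educators_explorative": 0,
        "n_educators_focused": 0,
        "trial_ms": 10_000,
    },
    "inputs": None,  # {"fixations": path, "pupil": path, "meta": path} to skip generation
    "fit": {"k_range": [1, 2, 3, 4], "n_restarts": 20},
    "cluster": {"n_clusters": 2, "n_init": 4, "rep_n_restarts": 5},
    "pupil": {"bin_ms": 300, "trial_ms": 10_000, "delta_mm_max": 0.5,
              "bin_invalid_frac": 0.5},
    "heatmap": {"bandwidth_px": 50.0, "grid": [54, 96]},
    "fixed_roi": {"ellipses": None},  # None -> default tooth ROIs from the layout
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML or JSON config file merged over the defaults."""
    if path is None:
        return merge_config(DEFAULT_CONFIG, {})
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(user).__name__}")
    return merge_config(DEFAULT_CONFIG, user)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
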