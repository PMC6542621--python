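"""Flat configuration files (JSON or YAML) mapping onto the parameter set."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml

from .params import ModelParameters, ConfigurationError, build_parameters
from dataclasses import asdict

__all__ = ["load_config", "dump_config"]


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[dict] = None) -> ModelParameters:
    """Resolve parameters with precedence CLI overrides > file > defaults.

    The file is flat: keys are :class:`ModelParameters` field names (the
    inhibitory-plasticity block may be flat or nested under ``inhibitory``).
    An empty or missing-content file yields the defaults.
    """
    merged: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        try:
            data = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {p}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {p} must be a flat mapping")
        merged.update(data)
    merged.update(overrides or {})
    return build_parameters(merged)


def dump_config(params: ModelParameters, path: str | Path) -> None:
    """Write the fully resolved parameter set as JSON (a YAML subset)."""
    Path(path).write_text(json.dumps(asdict(params), indent=2, sort_keys=True))
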