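"""Flat key-value configuration files and run provenance records.

The config format is deliberately minimal: one ``key = value`` pair per
line, ``#`` comments, no sections. Every CLI flag has a config equivalent
and CLI values override config values.
"""
from __future__ import annotations

import datetime
import json
from pathlib import Path

from .exceptions import ConfigError
from .io import ResidueSelection

__version__ = "0.1.0"


class AnalysisConfig:
    """Typed access to a flat key-value parameter file."""

    def __init__(self, values: dict[str, str] | None = None):
        self.values: dict[str, str] = dict(values or {})

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        values: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        cfg = cls(values)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Distance cutoffs/radii must be positive; seeds must be integers."""
        for key, val in self.values.items():
            if key.endswith(("_cutoff", "_radius", "cutoff", "radius")):
                if self.get_float(key) <= 0:
                    raise ConfigError(f"{key} must be > 0, got {val}")
            if key.endswith("seed"):
                try:
                    int(val)
                except ValueError:
                    raise ConfigError(f"{key} must be an integer, got {val!r}") from None

    def get(self, key: str, default=None) -> str | None:
        return self.values.get(key, default)

    def get_float(self, key: str, default: float | None = None) -> float:
        val = self.values.get(key)
        if val is None:
            if default is None:
                raise ConfigError(f"missing config key {key!r}")
            return default
        try:
            return float(val)
        except ValueError:
            raise ConfigError(f"{key} is not a number: {val!r}") from None

    def get_int(self, key: str, default: int | None = None) -> int:
        val = self.values.get(key)
        if val is None:
            if default is None:
                raise ConfigError(f"missing config key {key!r}")
            return default
        try:
            return int(val)
        except ValueError:
            raise ConfigError(f"{key} is not an integer: {val!r}") from None

    def get_selection(self, key: str, default: str | None = None) -> ResidueSelection:
        val = self.values.get(key, default)
        if val is None:
            raise ConfigError(f"missing config key {key!r}")
        return ResidueSelection.from_string(val)

    def merged_with(self, overrides: dict) -> "AnalysisConfig":
        """New config with CLI overrides applied (None values ignored)."""
        merged = dict(self.values)
        merged.update({k: str(v) for k, v in overrides.items() if v is not None})
        return AnalysisConfig(merged)


def write_provenance(out_dir, *, command: str, inputs: dict, parameters: dict,
                     seed: int | None) -> Path:
    """Write a provenance header (inputs, parameters, seed, version) for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": f"ptpkit {__version__}",
        "command": command,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": {k: str(v) for k, v in parameters.items()},
        "seed": seed,
    }
    path = out_dir / "run_provenance.json"
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
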