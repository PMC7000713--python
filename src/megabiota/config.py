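"""Flat key-value configuration files and run manifests.

One flat YAML mapping drives the whole pipeline; every documented key maps
onto a field of one of the package's parameter types.  A run manifest records
what a command produced: the command name, a content digest of the resolved
configuration (stable under key reordering), the seed, the output paths, and
a timestamp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = ["load_config", "save_config", "config_digest", "RunManifest"]


def load_config(path: str | Path) -> dict:
    """Load a flat key-value configuration file (YAML mapping, depth 1)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration must be a flat mapping: {path}")
    for key, value in data.items():
        if isinstance(value, (dict, list)):
            raise ValueError(f"configuration key {key!r} is not a scalar")
    return data


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_digest(config: dict) -> str:
    """SHA-256 digest of the resolved configuration, stable under reordering."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline command: inputs digest, seed, outputs, time."""

    command: str
    config_digest: str
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def validate_outputs(self) -> None:
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")

    def write(self, path: str | Path) -> None:
        self.validate_outputs()
        with open(path, "w") as fh:
            json.dump(
                {
                    "command": self.command,
                    "config_digest": self.config_digest,
                    "seed": self.seed,
                    "outputs": self.outputs,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
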