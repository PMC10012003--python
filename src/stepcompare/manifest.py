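"""Run manifests: auditable records tying outputs to config and seed.

Commands that generate data write a ``manifest.json`` next to their outputs
with the configuration hash, master seed, package version, file checksums and
a timestamp.  Under a fixed seed and config the generated files are
byte-identical, so the checksums make reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    inputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @property
    def config_digest(self) -> str:
        return config_hash(self.config)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config_hash": self.config_digest,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
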