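"""Run manifests: enough structured metadata to replay any command."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a JSON manifest next to a command's outputs and return its path."""
    from . import __version__

    manifest = {
        "tool": "careflow",
        "version": __version__,
        "command": command,
        "argv": sys.argv,
        "config": config,
        "master_seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _digest(Path(p))}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    out_path = Path(out_path)
    out_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out_path
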