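"""Run records and CSV report writers backing the CLI."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .config_io import write_config
from .parameters import ParameterBundle

__all__ = ["RunRecord", "config_digest", "file_digest"]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_digest(bundle: ParameterBundle, tmp_dir: str | Path) -> str:
    """Digest of the canonical YAML serialisation of a bundle."""
    tmp = Path(tmp_dir) / "_config_digest.yaml"
    write_config(bundle, tmp)
    digest = file_digest(tmp)
    tmp.unlink()
    return digest


@dataclass
class RunRecord:
    """Provenance for one CLI invocation.

    Output digests are reproducible for deterministic stages re-run with
    the same config digest and seed (the timestamp is informational only).
    """

    command: str
    config_digest: str
    master_seed: int
    package_version: str
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    timestamp: str = ""

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = file_digest(p)

    def write(self, out_dir: str | Path) -> Path:
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = Path(out_dir) / "run_record.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
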