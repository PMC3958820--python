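"""Run manifests: full provenance for every produced table.

The manifest is written before the first cycle and records the configuration
snapshot, the master seed, the package version, and SHA-256 checksums of
every input file, so any result can be regenerated from (manifest, seed)
alone.  Timestamps appear only here and in logs, never inside data files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from ..errors import LipidMCError


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    code_version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    start_cycle: int = 0
    end_cycle: int | None = None
    created: str = ""

    @classmethod
    def create(cls, config: dict, seed: int, inputs: dict[str, str | Path]):
        from lipidmc import __version__

        return cls(
            config=config,
            seed=seed,
            code_version=__version__,
            input_checksums={k: sha256_of(v) for k, v in inputs.items()},
            created=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify_inputs(self, inputs: dict[str, str | Path]):
        for k, v in inputs.items():
            expect = self.input_checksums.get(k)
            got = sha256_of(v)
            if expect != got:
                raise LipidMCError(
                    f"checksum mismatch for {k}: manifest {expect}, file {got}"
                )
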