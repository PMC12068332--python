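"""Run manifests: everything needed to reproduce a run's outputs.

A manifest records the resolved configuration (defaults filled in), every
seed, the package version, wall-clock bounds and a SHA-256 inventory of the
files the run wrote.  Deterministic backends reproduce outputs byte-for-byte
from (manifest, inputs); stochastic observables reproduce statistically.
"""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: list
    version: str
    started: str = ""
    finished: str = ""
    files: dict = field(default_factory=dict)  # relative path -> sha256

    @classmethod
    def start(cls, config: dict, seeds) -> "RunManifest":
        from . import __version__

        return cls(
            config=config,
            seeds=list(seeds),
            version=__version__,
            started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def add_file(self, path, base=None) -> None:
        rel = str(Path(path).relative_to(base)) if base else str(path)
        self.files[rel] = sha256_of(path)

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "version": self.version,
                    "started": self.started,
                    "finished": self.finished,
                    "files": self.files,
                },
                fh,
                sort_keys=False,
            )


def read_manifest(path) -> RunManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunManifest(
        config=raw["config"],
        seeds=raw["seeds"],
        version=raw["version"],
        started=raw.get("started", ""),
        finished=raw.get("finished", ""),
        files=raw.get("files", {}),
    )
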