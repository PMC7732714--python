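"""Run configuration and deterministic seed fan-out.

A single global seed is derived into per-stage seeds via a stable hash of
the stage name, so any stage can be rerun in isolation and still see the
same randomness as the full pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) + zlib.crc32(stage.encode("utf-8"))) % (2 ** 31)


@dataclass
class RunConfig:
    """Serializable description of one end-to-end run."""

    seed: int = 0
    output_dir: str = "runs/latest"
    corpus_path: str | None = None
    truth_path: str | None = None
    annotations_path: str | None = None
    generator: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    models: list[dict] = field(default_factory=list)
    cases: list[str] = field(default_factory=lambda: ["C1", "C2"])
    sample: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__},
                           fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__},
                              sort_keys=True)
        return format(zlib.crc32(blob.encode("utf-8")), "08x")
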