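"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    pixel_size: float = 0.1  # um/px
    gate_min: float = 0.4  # um
    gate_max: float = 2.0  # um
    coloc_cutoff: float = 0.5  # um
    positive_threshold: int = 6
    frap_eval_time: float = 60.0  # s
    stats_alpha: float = 0.05
    illumination_order: int = 2
    per_cell_threshold: bool = False
    n_images: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("pixel_size", "gate_min", "gate_max", "coloc_cutoff",
                     "frap_eval_time", "stats_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gate_min > self.gate_max:
            raise ValueError("gate_min must be <= gate_max")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
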