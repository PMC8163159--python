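"""Run configuration: every tunable threshold with its published default."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # site calling
    min_intensity: float = 0.20  # minimum RTa stop fraction
    min_reads: int = 10  # minimum coverage for any call
    min_conf_phred: float = 20.0  # misincorporation confidence threshold
    error_rate: float = 0.01  # null per-base mismatch rate
    tgirt_window: int = 3  # artifact echo window, nt 3' of the primary site
    # read retention
    read_min_len: int = 8
    read_max_len: int = 95
    qual_cutoff: int = 25
    mapping_accuracy_pct: float = 80.0
    pre_trna_margin: int = 1  # nt outside mature bounds marking a precursor read
    # classification
    weak_strong_boundary: float = 0.4
    # simulator
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_intensity <= 1.0:
            raise ValueError("min_intensity must be in [0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_conf_phred < 0:
            raise ValueError("min_conf_phred must be >= 0")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.tgirt_window < 0:
            raise ValueError("tgirt_window must be >= 0")
        if not 0 < self.read_min_len <= self.read_max_len:
            raise ValueError("read length window invalid")
        if not 0 <= self.mapping_accuracy_pct <= 100:
            raise ValueError("mapping_accuracy_pct must be in [0, 100]")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def override(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
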