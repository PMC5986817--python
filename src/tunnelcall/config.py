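"""Pipeline configuration: one schema-versioned object holding every
module default, round-trippable through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputError
from .trace_sim import ConductanceModel, TranslocationModel

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0

    # acquisition
    sample_rate_hz: float = 10_000.0
    bias_v: float = 0.1

    # detection
    baseline_window: int = 2000
    sigma_window: int = 20
    rise_sigma: float = 6.0
    fall_sigma: float = 1.0
    min_retention_ms: float = 0.5

    # calling
    interval_ms: float = 0.5
    expected_dwell_ms: float = 1.0 / 1.5
    n_bases: int = 3
    labels_by_rank: tuple = ("T", "A", "G")

    # assembly / quantitation
    min_fragment_len: int = 5
    min_overlap: int = 4
    max_mismatch: int = 0
    trim_end_frac: float = 0.05
    # the let-7 markers are 22-base molecules; the known molecule length
    # constrains consensus selection (None disables the constraint)
    target_length: int | None = 22

    # simulator models (flattened for serialization friendliness)
    conductance: dict = field(default_factory=lambda: {
        "means": {"T": 45.0, "A": 77.0, "G": 102.0},
        "sds": {"T": 8.0, "A": 8.0, "G": 8.0},
        "baseline_mean": 0.0,
        "baseline_sd": 4.0,
    })
    translocation: dict = field(default_factory=lambda: asdict(TranslocationModel()))

    def __post_init__(self) -> None:
        for name in ("sample_rate_hz", "baseline_window", "sigma_window",
                     "rise_sigma", "fall_sigma", "min_retention_ms",
                     "interval_ms", "expected_dwell_ms", "min_fragment_len",
                     "min_overlap", "trim_end_frac"):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise InputError(f"config field {name} must be non-negative")
        for name in ("sample_rate_hz", "baseline_window", "sigma_window",
                     "rise_sigma", "interval_ms", "min_fragment_len"):
            if getattr(self, name) <= 0:
                raise InputError(f"config field {name} must be positive")
        self.labels_by_rank = tuple(self.labels_by_rank)

    # model objects ---------------------------------------------------
    def conductance_model(self) -> ConductanceModel:
        return ConductanceModel(**self.conductance)

    def translocation_model(self) -> TranslocationModel:
        return TranslocationModel(**self.translocation)

    # serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["labels_by_rank"] = list(self.labels_by_rank)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


__all__ = ["PipelineConfig", "SCHEMA_VERSION"]
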