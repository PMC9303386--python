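"""Pipeline configuration: every numeric constant of the analysis lives
here, in one flat, serializable key space with CLI overrides."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .intervals import DEFAULT_MASK_BIOTYPES


@dataclass
class PipelineConfig:
    # geometry
    window: int = 40_000  # non-overlapping genome windows (bp)
    upstream: int = 3_000  # genic-mask extension before the TSS (bp)
    downstream: int = 10_000  # genic-mask extension past the TES (bp)
    # normalization
    norm_total: int = 10_000_000  # coverage normalized to 10 million reads
    rpm_floor: float = 5.0  # repeat-family inclusion floor (reads/million)
    # testing thresholds
    alpha: float = 0.01
    lfc_genes: float = 1.0
    lfc_pirna: float = 0.5
    lfc_repeats: float = 0.5
    # metaprofiles
    flank: int = 2_000
    bin_size: int = 50
    # misc
    seed: int = 0
    mask_biotypes: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_MASK_BIOTYPES)
    )

    def __post_init__(self):
        for key in ("window", "upstream", "downstream", "norm_total", "flank", "bin_size"):
            if getattr(self, key) < 0 or (key in ("window", "norm_total", "bin_size") and getattr(self, key) == 0):
                raise ValueError(f"{key} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rpm_floor < 0:
            raise ValueError("rpm_floor must be non-negative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
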