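"""Run configuration with the published defaults (T=75, L1, replicate)."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .detector import DEFAULT_THRESHOLD, _BORDER_MODES
from .vmf import NORMS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Defaults reproduce the reference settings of the method.

    threshold : detection threshold T on the minimum variation (both rounds).
    norm : vector-median distance norm, L1 (integer-exact) or L2.
    border : convolution border policy; replicate keeps border responses clean.
    noise_mode : monochrome (per-pixel impulses) or channelwise.
    salt_fraction : share of impulses at 255.
    seed : master seed; all randomness flows from it.
    log_level : logging verbosity for the CLI.
    """

    threshold: float = DEFAULT_THRESHOLD
    norm: str = "L1"
    border: str = "replicate"
    noise_mode: str = "monochrome"
    salt_fraction: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}, got {self.norm!r}")
        if self.border not in _BORDER_MODES:
            raise ValueError(f"border must be one of {sorted(_BORDER_MODES)}, got {self.border!r}")
        if self.noise_mode not in ("monochrome", "channelwise"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise ValueError(f"salt_fraction must be in [0, 1], got {self.salt_fraction}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def as_dict(self) -> dict:
        return asdict(self)
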