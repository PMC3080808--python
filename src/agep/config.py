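"""Run configuration shared by all agep commands.

Every tunable of the method lives here so that outputs can carry a single
provenance hash: the density grid resolution, the minimum number of samples a
tissue needs before it is modelled, the ts-score scaling factor phi, the
typicality significance level alpha, the ts threshold used when counting
tissue-specific genes, and the peak-area threshold of the modality detector.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

from .exceptions import ConfigurationError


@dataclasses.dataclass(frozen=True)
class Config:
    grid_size: int = 512
    min_tissue_size: int = 6
    phi: float = 0.25
    alpha: float = 0.05
    ts_threshold: float = 0.75
    peak_area_threshold: float = 0.1
    ambiguous_modality_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ConfigurationError("grid_size must be at least 2")
        if self.min_tissue_size < 2:
            raise ConfigurationError("min_tissue_size must be at least 2")
        if not self.phi > 0:
            raise ConfigurationError("phi must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not -1 <= self.ts_threshold <= 1:
            raise ConfigurationError("ts_threshold must lie in [-1, 1]")
        if not 0 < self.peak_area_threshold < 1:
            raise ConfigurationError("peak_area_threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    @property
    def hash(self) -> str:
        """Short digest of the canonical JSON form, embedded in output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
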