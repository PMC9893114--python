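"""Pipeline configuration with strict YAML round-trip.

All numeric defaults are the method's published operating point: detection
window M = 10 samples with margin h = 30 units, rate window delta_n = 5120
samples, amplification gamma = 1000, sampling rate 512 Hz.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class DetectionConfig:
    M: int = 10
    h: float = 30.0

    def validate(self) -> None:
        if self.M < 2 or self.h < 0:
            raise ConfigurationError("detection: need M >= 2 and h >= 0")


@dataclass
class NetworkConfig:
    delta_n: int = 5120
    stride: int = 5120
    gamma: float = 1000.0
    normalization_mode: str = "sqrt_mm"

    def validate(self) -> None:
        if self.delta_n < 1 or self.stride < 1:
            raise ConfigurationError("network: delta_n and stride must be >= 1")
        if self.normalization_mode not in ("sqrt_mm", "product_mm"):
            raise ConfigurationError("network: unknown normalization_mode")


@dataclass
class EigenConfig:
    hsb_normalization: str = "ratio"
    band_boundaries: tuple = (1.0, 2.0)  # multiples of SD above AVG

    def validate(self) -> None:
        if self.hsb_normalization not in ("ratio", "global_max"):
            raise ConfigurationError("eigen: unknown hsb_normalization")
        if list(self.band_boundaries) != sorted(self.band_boundaries):
            raise ConfigurationError("eigen: band boundaries must be ascending")


@dataclass
class KdeConfig:
    bandwidth: str = "silverman"
    grid_size: int = 512

    def validate(self) -> None:
        if self.grid_size < 16:
            raise ConfigurationError("kde: grid_size too small")


@dataclass
class PlungeConfig:
    threshold: float = 0.3
    splits_per_phase: int = 2

    def validate(self) -> None:
        if not (0 < self.threshold <= 2):
            raise ConfigurationError("plunge: threshold must be in (0, 2]")
        if self.splits_per_phase < 1:
            raise ConfigurationError("plunge: splits_per_phase must be >= 1")


@dataclass
class PipelineConfig:
    """Top-level configuration; unknown keys in a YAML file are rejected."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    eigen: EigenConfig = field(default_factory=EigenConfig)
    kde: KdeConfig = field(default_factory=KdeConfig)
    plunge: PlungeConfig = field(default_factory=PlungeConfig)
    fs: float = 512.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        for section in (self.detection, self.network, self.eigen, self.kde, self.plunge):
            section.validate()

    # -- round trip ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eigen"]["band_boundaries"] = list(d["eigen"]["band_boundaries"])
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sections = {
            "detection": DetectionConfig,
            "network": NetworkConfig,
            "eigen": EigenConfig,
            "kde": KdeConfig,
            "plunge": PlungeConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            if name in raw:
                sub = raw.pop(name)
                allowed = {f.name for f in fields(section_cls)}
                unknown = set(sub) - allowed
                if unknown:
                    raise ConfigurationError(f"{name}: unknown keys {sorted(unknown)}")
                if "band_boundaries" in sub:
                    sub["band_boundaries"] = tuple(sub["band_boundaries"])
                kwargs[name] = section_cls(**sub)
        top_allowed = {"fs", "seed"}
        unknown = set(raw) - top_allowed
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        kwargs.update(raw)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        """Short stable hash of the configuration (stamped onto outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
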