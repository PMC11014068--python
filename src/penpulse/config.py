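"""Run configuration: strict, YAML-loadable parameter bundles."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .events import PeakParams
from .io import ScaleConfig


@dataclass(frozen=True)
class FilterParams:
    order: int = 4
    cutoff_hz: float = 2.0
    zero_phase: bool = True


@dataclass(frozen=True)
class MatchingParams:
    max_offset: float = 1.0
    estimate_shift: bool = False


@dataclass(frozen=True)
class DetrendParams:
    method: str | None = "mean"  # None runs the filter on the raw offset magnitude
    window: float | None = None


@dataclass(frozen=True)
class RunConfig:
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    matching: MatchingParams = field(default_factory=MatchingParams)
    detrend: DetrendParams = field(default_factory=DetrendParams)
    seed: int = 0

    _SECTIONS = {
        "scale": ScaleConfig,
        "filter": FilterParams,
        "peaks": PeakParams,
        "matching": MatchingParams,
        "detrend": DetrendParams,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a nested dict, rejecting unknown keys at every level."""
        d = dict(d or {})
        known = set(cls._SECTIONS) | {"seed"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        kwargs = {}
        for section, section_cls in cls._SECTIONS.items():
            sub = dict(d.get(section) or {})
            names = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(sub) - names
            if bad:
                raise ParameterError(
                    f"unknown key(s) in section {section!r}: {', '.join(sorted(bad))}"
                )
            kwargs[section] = section_cls(**sub)
        seed = d.get("seed", 0)
        if not isinstance(seed, int):
            raise ParameterError(f"seed must be an integer, got {seed!r}")
        return cls(seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParameterError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        """Hash of the canonical JSON form, for run manifests."""
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()
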