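"""Pipeline configuration: one validated tree with full defaulting.

Loadable from YAML/JSON-compatible nested mappings; every leaf falls back
to the default stated in its owning module.  The effective configuration is
echoed into output metadata for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .core import DEFAULT_RATE_BAND, RadarConfig

__all__ = ["DspConfig", "VitalsConfig", "AgreementConfig", "PipelineConfig"]


@dataclass(frozen=True)
class DspConfig:
    window: str = "hann"
    zero_pad_factor: int = 4
    roi: tuple[float, float] = (0.2, 1.2)
    noise_floor_multiple: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi", tuple(self.roi))
        if self.zero_pad_factor < 1:
            raise ValueError(f"zero_pad_factor must be >= 1, got {self.zero_pad_factor}")
        if not self.roi[0] < self.roi[1]:
            raise ValueError(f"roi must satisfy min < max, got {self.roi}")
        if not self.noise_floor_multiple > 0:
            raise ValueError("noise_floor_multiple must be positive")


@dataclass(frozen=True)
class VitalsConfig:
    band: tuple[float, float] = (0.1, 2.0)
    prominence: float = 0.5
    rate_window: float = 30.0
    rate_step: float = 1.0
    apnea_min_duration: float = 10.0
    apnea_rms_fraction: float = 0.3
    rms_window: float = 1.0
    rate_band: tuple[float, float] = DEFAULT_RATE_BAND

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", tuple(self.band))
        object.__setattr__(self, "rate_band", tuple(self.rate_band))
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        for name in ("prominence", "rate_window", "rate_step", "apnea_min_duration",
                     "rms_window"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.apnea_rms_fraction < 1):
            raise ValueError("apnea_rms_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class AgreementConfig:
    max_lag: float = 30.0
    grid_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if not self.grid_rate > 0:
            raise ValueError("grid_rate must be positive")


def _tupleize(obj):
    if isinstance(obj, tuple):
        return list(obj)
    return obj


@dataclass(frozen=True)
class PipelineConfig:
    radar: RadarConfig = field(default_factory=RadarConfig)
    dsp: DspConfig = field(default_factory=DspConfig)
    vitals: VitalsConfig = field(default_factory=VitalsConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)

    def to_dict(self) -> dict:
        d = {
            "radar": self.radar.to_dict(),
            "dsp": dataclasses.asdict(self.dsp),
            "vitals": dataclasses.asdict(self.vitals),
            "agreement": dataclasses.asdict(self.agreement),
        }
        for section in d.values():
            for k, v in section.items():
                section[k] = _tupleize(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sections = {"radar": RadarConfig.from_dict, "dsp": DspConfig,
                    "vitals": VitalsConfig, "agreement": AgreementConfig}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, builder in sections.items():
            payload = d.get(name, {})
            if name == "radar":
                kwargs[name] = builder(payload)
            else:
                known = {f.name for f in dataclasses.fields(builder)}
                bad = set(payload) - known
                if bad:
                    raise ValueError(f"unknown {name} config fields: {sorted(bad)}")
                kwargs[name] = builder(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in payload.items()})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
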