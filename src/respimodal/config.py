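"""Pipeline configuration with validated defaults.

Every numeric default is the value used throughout the analysis; all of
them are overridable from YAML/JSON config files or keyword arguments.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the key."""


@dataclass
class IPConfig:
    """Impedance-pneumography branch parameters."""

    resample_hz: float = 100.0
    artifact_hi: float = 1.5  # reject samples > artifact_hi * median
    artifact_lo: float = 0.5  # reject samples < artifact_lo * median
    bp_lo_hz: float = 0.1
    bp_hi_hz: float = 1.0  # raised up to 1.4 for fast breathers
    detect_win_s: float = 32.0
    detect_overlap_s: float = 2.0
    min_peak_dist_s: float = 0.67  # RR < 89.55 bpm
    peak_dedup_s: float = 0.25
    sqi_win_s: float = 32.0
    sqi_overlap: float = 0.75
    sqi_cov: float = 0.3
    sqi_corr: float = 0.7
    sqi_coverage: float = 0.6
    #: time-normalize each breath to the median IBI before template
    #: correlation; False compares raw-duration, start-aligned breaths
    sqi_time_normalize: bool = False
    mad_k: float = 5.0
    mad_window: int = 30

    def validate(self) -> None:
        if self.bp_lo_hz <= 0 or self.bp_hi_hz <= self.bp_lo_hz:
            raise ConfigError("ip.bp_lo_hz/bp_hi_hz: need 0 < bp_lo_hz < bp_hi_hz")
        if not (1.0 <= self.bp_hi_hz <= 1.4):
            warnings.warn(
                f"ip.bp_hi_hz={self.bp_hi_hz} outside nominal [1.0, 1.4] Hz",
                stacklevel=2,
            )
        if self.min_peak_dist_s <= 0:
            raise ConfigError("ip.min_peak_dist_s must be positive")
        if self.mad_window < 1:
            raise ConfigError("ip.mad_window must be >= 1")


@dataclass
class LSConfig:
    """Lung-sound branch parameters."""

    resample_hz: float = 4000.0
    bp_lo_hz: float = 100.0
    bp_hi_hz: float = 1000.0
    psd_win_ms: float = 64.0
    psd_overlap: float = 0.75
    bands: tuple[tuple[float, float], ...] = (
        (100.0, 300.0),
        (300.0, 500.0),
        (500.0, 800.0),
        (800.0, 1000.0),
    )
    mad_k: float = 4.0
    mad_window: int = 30
    per_window_si: bool = True  # average per-window SIs vs SI of averaged PSD

    def validate(self) -> None:
        if self.bp_hi_hz >= self.resample_hz / 2:
            raise ConfigError("ls.bp_hi_hz must be below Nyquist")
        bands = [tuple(map(float, b)) for b in self.bands]
        for lo, hi in bands:
            if hi <= lo:
                raise ConfigError(f"ls.bands: band ({lo}, {hi}) has hi <= lo")
        for (_, hi_prev), (lo_next, _) in zip(bands, bands[1:]):
            if lo_next < hi_prev:
                raise ConfigError("ls.bands: bands overlap")
            if lo_next > hi_prev:
                raise ConfigError("ls.bands: bands leave a gap")
        if not 0 <= self.psd_overlap < 1:
            raise ConfigError("ls.psd_overlap must be in [0, 1)")


@dataclass
class FusionConfig:
    """Feature time-series windowing parameters."""

    win_s: float = 32.0
    overlap: float = 0.75
    mad_k: float = 5.0
    per_feature: bool = True  # outlier removal per feature vs whole window

    def validate(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ConfigError("fusion.overlap must be in [0, 1)")
        if self.win_s <= 0:
            raise ConfigError("fusion.win_s must be positive")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    bh_m: int = 2  # BH family: the two group comparisons per feature

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("stats.alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Top-level configuration for the whole pipeline."""

    ip: IPConfig = field(default_factory=IPConfig)
    ls: LSConfig = field(default_factory=LSConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    scaled_mad: bool = True

    def validate(self) -> "PipelineConfig":
        self.ip.validate()
        self.ls.validate()
        self.fusion.validate()
        self.stats.validate()
        return self

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ls"]["bands"] = [list(b) for b in self.ls.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (("ip", IPConfig), ("ls", LSConfig),
                          ("fusion", FusionConfig), ("stats", StatsConfig)):
            if name in d:
                sub_d = dict(d.pop(name))
                if name == "ls" and "bands" in sub_d:
                    sub_d["bands"] = tuple(tuple(map(float, b)) for b in sub_d["bands"])
                known = {f.name for f in dataclasses.fields(sub)}
                unknown = set(sub_d) - known
                if unknown:
                    raise ConfigError(f"{name}: unknown config keys {sorted(unknown)}")
                kwargs[name] = sub(**sub_d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**kwargs, **d)
        return cfg.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


def band_edges(bands: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Overall (lo, hi) span of a contiguous band partition."""
    return float(bands[0][0]), float(bands[-1][1])
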