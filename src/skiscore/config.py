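"""Pipeline configuration: every tunable threshold in one place.

Defaults are loaded from the dataclasses below; a YAML file with the same
nested keys overrides them, e.g.::

    segmentation:
      lowpass_hz: 2.0
      min_prominence_dps: 15.0
    enrich:
      alpha: 0.98
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SegmentationConfig:
    #: zero-phase Butterworth low-pass cutoff applied to the roll-rate signal, Hz
    lowpass_hz: float = 2.0
    #: minimum prominence of a roll-rate extremum to count as a turn transition, dps
    min_prominence_dps: float = 15.0
    #: minimum turn duration / extremum separation, s
    min_period_s: float = 0.6
    #: which boot's roll gyro drives segmentation
    source_boot: str = "left"


@dataclass
class FilterConfig:
    #: apply the median - MAD slow-turn exclusion rule
    mad_rule: bool = True


@dataclass
class EnrichConfig:
    #: complementary-filter gyro weight (at the nominal 54 Hz rate)
    alpha: float = 0.98
    #: which boot feeds edge angle: outside boot of the turn, or mean of both
    edge_boot: str = "outside"


@dataclass
class ClassifyConfig:
    #: minimum mean edge angle (deg) for the naive carving rule
    carve_angle_min: float = 30.0
    #: "turn" = per-turn radius thresholds; "run" = honour run-level intended size
    size_from: str = "turn"
    #: "auto" = naive classifier when no label given; "intended" = use run code
    style_from: str = "auto"


@dataclass
class ModelConfig:
    #: number of retained principal components (fixed to 3 by the scoring design)
    n_components: int = 3
    #: minimum reference turns per (style, size) cell
    min_ref_turns: int = 10


@dataclass
class IOConfig:
    #: clip out-of-full-scale samples (with a warning) instead of rejecting the file
    clip_out_of_range: bool = True


@dataclass
class Config:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None) -> Config:
    """Build a Config from defaults, overridden by an optional YAML file."""
    cfg = Config()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    for section, values in data.items():
        if not hasattr(cfg, section):
            raise ConfigError(f"unknown config section {section!r}")
        sub = getattr(cfg, section)
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must hold a mapping")
        for key, value in values.items():
            if not hasattr(sub, key):
                raise ConfigError(f"unknown config key {section}.{key}")
            setattr(sub, key, value)
    _validate(cfg)
    return cfg


def _validate(cfg: Config) -> None:
    if cfg.segmentation.lowpass_hz <= 0 or cfg.segmentation.min_prominence_dps <= 0:
        raise ConfigError("segmentation thresholds must be positive")
    if cfg.segmentation.min_period_s <= 0:
        raise ConfigError("segmentation.min_period_s must be positive")
    if not 0 < cfg.enrich.alpha < 1:
        raise ConfigError("enrich.alpha must lie in (0, 1)")
    if cfg.enrich.edge_boot not in ("outside", "mean"):
        raise ConfigError("enrich.edge_boot must be 'outside' or 'mean'")
    if cfg.classify.size_from not in ("turn", "run"):
        raise ConfigError("classify.size_from must be 'turn' or 'run'")
    if cfg.classify.style_from not in ("auto", "intended"):
        raise ConfigError("classify.style_from must be 'auto' or 'intended'")
    if cfg.model.min_ref_turns < 2:
        raise ConfigError("model.min_ref_turns must be at least 2")
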