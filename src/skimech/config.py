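"""Validated run configuration (YAML), with per-module sections.

All analysis thresholds live here with their defaults: the 1 cm segmentation
threshold, 101-sample time normalization, 90% PCA variance retention and the
0.05 significance level. Unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SegmentationConfig:
    threshold_mm: float = 10.0
    n_samples: int = 101
    min_cycle_samples: int = 4
    max_cycle_s: float = 10.0


@dataclass
class PcaConfig:
    retention: float = 0.9  # fraction of variance retained


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class ClassifierConfig:
    c: float = 1.0
    folds: int = 5


@dataclass
class TrackConfig:
    gate_radius_m: float = 5.0
    n_resample: int = 400


@dataclass
class RunConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    track: TrackConfig = field(default_factory=TrackConfig)


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for key, value in data.items():
        expected = fields[key].type
        if expected in ("float", float) and isinstance(value, (int, float)) \
                and not isinstance(value, bool):
            kwargs[key] = float(value)
        elif expected in ("int", int) and isinstance(value, int) and not isinstance(value, bool):
            kwargs[key] = value
        else:
            raise ValueError(f"config key '{path}.{key}': expected {expected}, got {value!r}")
    return cls(**kwargs)


def _validate(cfg: RunConfig) -> RunConfig:
    if not 0 < cfg.pca.retention <= 1:
        raise ValueError(f"pca.retention must be in (0, 1], got {cfg.pca.retention}")
    if not 0 < cfg.stats.alpha < 1:
        raise ValueError(f"stats.alpha must be in (0, 1), got {cfg.stats.alpha}")
    if cfg.segmentation.threshold_mm < 0:
        raise ValueError("segmentation.threshold_mm must be nonnegative")
    if cfg.segmentation.n_samples < 4:
        raise ValueError("segmentation.n_samples must be at least 4")
    if cfg.classifier.folds < 2:
        raise ValueError("classifier.folds must be at least 2")
    return cfg


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; an empty/missing file means all defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config root must be a mapping")
    sections = {f.name: f.default_factory() for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for name, body in data.items():
        if not isinstance(body, dict):
            raise ValueError(f"config section '{name}' must be a mapping")
        sections[name] = _build_section(type(sections[name]), body, name)
    return _validate(RunConfig(**sections))
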