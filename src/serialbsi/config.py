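"""Run configuration: a nested key/value (YAML) file driving the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .phantom import CohortSpec, NoiseSpec, PhantomSpec, ACCELERATED, NON_ACCELERATED


@dataclass(frozen=True)
class BsiSettings:
    dilate: int = 1
    erode: int = 1
    window_fraction: float = 0.25
    ventricle_window: tuple[float, float] = (0.25, 0.75)
    target_means: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    n_boot: int = 2000
    qc_n: int = 500
    qc_p_fail_a: float = 0.07
    qc_p_fail_na: float = 0.14
    qc_odds_ratio: float = 2.0
    rerate_flip_prob: float = 0.05


@dataclass(frozen=True)
class ImagingCohortSettings:
    """The image-based arm of the synthetic study."""

    n_subjects: int = 40
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0)
    rate_mean_ml_yr: float = 10.0      # AD-scale whole-brain loss
    rate_sd_ml_yr: float = 3.0
    visit_sd_ml: float = 0.3
    snr_accelerated: float = 25.0
    snr_gradient_accelerated: float = 0.01
    snr_non_accelerated: float = 30.0
    motion_severity_accelerated: float = 0.0
    motion_severity_non_accelerated: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    imaging: ImagingCohortSettings = field(default_factory=ImagingCohortSettings)
    bsi: BsiSettings = field(default_factory=BsiSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    return obj


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "phantom", "cohort", "imaging", "bsi", "stats"):
            sub_cls = {"phantom": PhantomSpec, "cohort": CohortSpec,
                       "imaging": ImagingCohortSettings, "bsi": BsiSettings,
                       "stats": StatsSettings}[f.name]
            kwargs[f.name] = _from_dict(sub_cls, v)
        else:
            kwargs[f.name] = _tuplify(v)
    return cls(**kwargs)


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(_to_dict(config), sort_keys=True)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config_to_yaml(config))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(RunConfig, data)


def apply_overrides(config: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply dotted ``key=value`` overrides, e.g. ``imaging.n_subjects=10``."""
    data = _to_dict(config)
    for item in overrides:
        key, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} must be key=value")
        node = data
        parts = key.strip().split(".")
        for p in parts[:-1]:
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = yaml.safe_load(raw)
    return _from_dict(RunConfig, data)
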