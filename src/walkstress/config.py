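"""Run configuration: one YAML file, flat per-stage namespaces.

Every default equals the published analysis constant where one exists
(0.01 µS mean-EDA screen, 25 SCR counts/min, 4 Hz IMU cutoff, 3 s STFT
window, 0.5 spectral amplitude, 15 s interruption minimum, 5-240 s
window sweep, 40 m buffer, 1-150 m segment lengths, 5 CV folds).
Unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .pipeline import PipelineParams
from .spatial import SEGMENT_LENGTHS_M
from .synth import StimulusEffect, SynthConfig

__all__ = ["RunConfig", "StatsConfig", "SpatialConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class StatsConfig:
    window_min_s: int = 5
    window_max_s: int = 240
    window_step_s: int = 1
    features: tuple[str, ...] = (
        "scl",
        "scr_amplitude",
        "scr_frequency",
        "stride_time",
        "mean_hr",
        "eda_psc",
        "imu_psc",
        "bvp_psc",
    )
    run_ttests: bool = True


@dataclass(frozen=True)
class SpatialConfig:
    segment_lengths_m: tuple[float, ...] = tuple(float(x) for x in SEGMENT_LENGTHS_M)
    buffer_m: float = 40.0
    n_folds: int = 5
    normalize_per_trip: bool = True
    group_by_subject: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)


def _build(cls, data: dict[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict):
            sub = {
                "synth": SynthConfig,
                "pipeline": PipelineParams,
                "stats": StatsConfig,
                "spatial": SpatialConfig,
                "stimulus_effect": StimulusEffect,
            }.get(key)
            if sub is None:
                raise ValueError(f"unexpected mapping at {path}.{key}")
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a RunConfig from YAML (or a pre-parsed mapping)."""
    if data is None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data, "config")


def dump_config(config: RunConfig) -> str:
    """Serialize to YAML; load_config round-trips the result unchanged."""

    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return yaml.safe_dump(clean(config), sort_keys=True)
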