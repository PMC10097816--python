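"""Canonical synthetic benchmarks used by the test-suite and examples.

Two matched study configurations share every nuisance parameter and
differ only in the injected stimulus response:

* strong-effect: 30 subjects with 5-10 trips each; each stimulus passage
  adds 3 extra SCRs of 0.5 µS, slows the stride period by 20 % and bumps
  heart rate by 8 bpm for 30 s.
* null: identical study with all effect magnitudes zero, so stimulus and
  non-stimulus locations are physiologically indistinguishable.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import spatial
from .pipeline import PipelineParams, extract_study_features, trip_feature_map
from .synth import StimulusEffect, SynthConfig, simulate_study

__all__ = [
    "strong_effect_config",
    "null_config",
    "small_sweep_config",
    "run_segment_benchmark",
]


def strong_effect_config(seed: int = 0, **overrides) -> SynthConfig:
    """The fixed strong-effect benchmark study."""
    cfg = SynthConfig(
        seed=seed,
        n_subjects=30,
        trips_per_subject=(5, 10),
        stimulus_effect=StimulusEffect(
            extra_scr_amp_uS=0.5, scr_burst_count=3, stride_slowdown_frac=0.2, hr_bump_bpm=8.0
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(seed: int = 0, **overrides) -> SynthConfig:
    """The matched null benchmark (zero injected effects)."""
    cfg = strong_effect_config(seed)
    cfg = replace(
        cfg,
        stimulus_effect=StimulusEffect(
            extra_scr_amp_uS=0.0, scr_burst_count=0, stride_slowdown_frac=0.0, hr_bump_bpm=0.0
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


def small_sweep_config(seed: int) -> SynthConfig:
    """Reduced strong-effect study for multi-seed segment-length sweeps."""
    return strong_effect_config(seed, n_subjects=12, trips_per_subject=(3, 6))


def run_segment_benchmark(
    config: SynthConfig,
    lengths: list[float] = (40.0,),
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    params: PipelineParams = PipelineParams(),
    cv_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a study, run the full pipeline and the segment classifier.

    Returns the sweep results table (one row per length and feature set).
    """
    trips, reports, _, streets = simulate_study(config)
    study = extract_study_features(trips, params)
    return spatial.sweep_segment_lengths(
        streets,
        trip_feature_map(study),
        reports,
        lengths=list(lengths),
        feature_sets=feature_sets,
        seed=cv_seed,
    )
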