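"""End-to-end orchestration: trips in, geocoded feature series out.

One call per trip runs the full per-channel chain (smooth/screen EDA,
filter IMU and excise interruptions, clean BVP and derive heart rate),
extracts the raw and saliency feature families, and geocodes every
series onto the GPS track. Study-level helpers fan this out over all
trips and hand the result to the spatial classification stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from . import preprocess as pp
from .io_formats import WalkingTrip, align_trip
from .preprocess import IntervalSet, QualityDecision

__all__ = ["PipelineParams", "TripFeatures", "process_trip", "extract_study_features"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable preprocessing/feature knobs (defaults are the study rules)."""

    bateman_tau1_s: float = 2.0
    bateman_tau2_s: float = 0.75
    bateman_length: int = 12
    imu_cutoff_hz: float = 4.0
    stft_window_s: float = pp.STFT_WINDOW_S
    spectral_amp_threshold: float = pp.SPECTRAL_AMP_THRESHOLD
    min_interruption_s: float = pp.MIN_INTERRUPTION_S
    bvp_passband_hz: tuple[float, float] = (0.6, 4.0)
    hr_smooth_beats: int = 5
    min_scr_amp_uS: float = ft.MIN_SCR_AMP_US
    psc_distance_weighted: bool = True
    psc_max_merge_cost: float | None = None  # None: 2 * series variance


@dataclass
class TripFeatures:
    """Per-trip pipeline output: QC decisions plus geocoded feature series."""

    trip_id: str
    subject_id: str
    duration_s: float
    eda_quality: QualityDecision
    interruptions: IntervalSet
    features: dict[str, ft.FeatureSeries] = field(default_factory=dict)
    track: object = None

    @property
    def usable(self) -> bool:
        return self.eda_quality.usable


def process_trip(trip: WalkingTrip, params: PipelineParams = PipelineParams()) -> TripFeatures:
    """Run the full per-trip chain and geocode every feature family.

    EDA features are omitted when the trip fails the usability screen;
    other channels are still processed (matching per-channel trip counts
    in field studies, where EDA dropouts do not discard gait or BVP).
    """
    trip = align_trip(trip)
    T = trip.duration_s
    out_features: dict[str, ft.FeatureSeries] = {}

    # --- IMU: filter, interruptions, stride time --------------------------
    acc = {k: pp.filter_imu(trip.channel(k), params.imu_cutoff_hz) for k in ("acc_x", "acc_y", "acc_z")}
    interruptions = pp.detect_interruptions(
        acc["acc_x"],
        acc["acc_y"],
        acc["acc_z"],
        window_s=params.stft_window_s,
        amp_threshold=params.spectral_amp_threshold,
        min_duration_s=params.min_interruption_s,
    )
    stride = ft.compute_stride_time(acc, interruptions)
    out_features["stride_time"] = stride
    out_features["imu_psc"] = ft.psc_series(
        stride, "imu_psc", params.psc_max_merge_cost, params.psc_distance_weighted
    )

    # --- EDA: smooth, SCRs, screen ----------------------------------------
    eda_s = pp.smooth_eda(
        trip.channel("eda"), params.bateman_tau1_s, params.bateman_tau2_s, params.bateman_length
    )
    scl, events = ft.detect_scrs(eda_s, params.min_scr_amp_uS)
    quality = pp.screen_eda(eda_s, events)
    if quality.usable:
        out_features["scl"] = scl
        amp, freq = ft.scr_feature_series(events, T)
        out_features["scr_amplitude"] = amp
        out_features["scr_frequency"] = freq
        out_features["eda_psc"] = ft.psc_series(
            ft.FeatureSeries("scl", eda_s.times(), eda_s.values),
            "eda_psc",
            params.psc_max_merge_cost,
            params.psc_distance_weighted,
        )

    # --- BVP: clean, heart rate -------------------------------------------
    bvp_c = pp.clean_bvp(trip.channel("bvp"), params.bvp_passband_hz)
    hr = pp.estimate_heart_rate(bvp_c, params.hr_smooth_beats)
    if len(hr) > 0:
        hr_series = ft.FeatureSeries("mean_hr", hr.timestamps, hr.bpm)
        out_features["mean_hr"] = hr_series
        out_features["bvp_psc"] = ft.psc_series(
            hr_series, "bvp_psc", params.psc_max_merge_cost, params.psc_distance_weighted
        )

    geocoded = {
        name: ft.geocode_features(series, trip.track) if len(series) else series
        for name, series in out_features.items()
    }
    return TripFeatures(
        trip_id=trip.trip_id,
        subject_id=trip.subject_id,
        duration_s=T,
        eda_quality=quality,
        interruptions=interruptions,
        features=geocoded,
        track=trip.track,
    )


def extract_study_features(
    trips: list[WalkingTrip], params: PipelineParams = PipelineParams()
) -> dict[str, TripFeatures]:
    """Process every trip; returns trip_id -> TripFeatures."""
    return {trip.trip_id: process_trip(trip, params) for trip in trips}


def trip_feature_map(study: dict[str, TripFeatures]) -> dict[str, dict[str, ft.FeatureSeries]]:
    """Reduce to the mapping the spatial stage consumes."""
    return {tid: tf.features for tid, tf in study.items()}


def trip_data_map(study: dict[str, TripFeatures]) -> dict[str, dict]:
    """Reduce to the mapping the window-statistics stage consumes."""
    return {
        tid: {
            "track": tf.track,
            "duration_s": tf.duration_s,
            "subject_id": tf.subject_id,
            "interruptions": tf.interruptions,
            "features": tf.features,
        }
        for tid, tf in study.items()
    }
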