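"""Synthetic walking-study generator.

Emulates a neighborhood-scale field study: subjects repeatedly walk routes
over a planar street grid wearing a wristband (EDA 4 Hz, BVP 64 Hz) and a
waist IMU (50 Hz) with GPS fixes every 3 s, and self-report the locations
and types of negative environmental stimuli they pass. Stimuli inject
multi-modal physiological effects of configurable magnitude shortly after
passage: a burst of extra skin-conductance responses, a lengthened stride
period, and a heart-rate bump. Reported locations carry isotropic Gaussian
error relative to the true stimulus position.

The generator is fully deterministic given the config seed; per-trip random
substreams are derived from it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString

from .io_formats import (
    GeoTrack,
    SignalChannel,
    StimulusReport,
    WalkingTrip,
    write_e4_channel,
    write_reports_csv,
    write_streets_geojson,
    write_track_csv,
)

__all__ = [
    "StimulusEffect",
    "SynthConfig",
    "GroundTruth",
    "TripTruth",
    "bateman",
    "make_street_network",
    "simulate_trip",
    "simulate_study",
]


@dataclass(frozen=True)
class StimulusEffect:
    """Injected physiological response to passing a negative stimulus."""

    extra_scr_amp_uS: float = 0.5
    scr_burst_count: int = 3
    stride_slowdown_frac: float = 0.2
    hr_bump_bpm: float = 8.0

    def is_null(self) -> bool:
        return (
            self.extra_scr_amp_uS == 0
            and self.scr_burst_count == 0
            and self.stride_slowdown_frac == 0
            and self.hr_bump_bpm == 0
        )


@dataclass(frozen=True)
class SynthConfig:
    """Study-level generator configuration.

    Defaults describe a desk-scale benchmark: a 5x5-node street grid
    (40 streets of 100 m), 300 s trips at 1.4 m/s, stimulus density
    2.5 per km, and effect magnitudes matching a clearly reactive
    pedestrian (3 extra SCRs of 0.5 µS, 20 % stride slowdown, +8 bpm)
    over a 30 s post-passage window.
    """

    seed: int = 0
    n_subjects: int = 30
    trips_per_subject: tuple[int, int] = (5, 10)
    trip_duration_s: float = 300.0
    walk_speed_mps: float = 1.4
    # gait
    step_freq_hz: float = 2.0
    step_amp_g: float = 0.8
    acc_noise_g: float = 0.05
    pause_prob: float = 0.2          # probability a trip contains one pause
    pause_duration_s: tuple[float, float] = (20.0, 40.0)
    # EDA
    tonic_base_uS: float = 2.0
    tonic_drift_uS: float = 0.15
    scr_base_rate_per_min: float = 3.0
    scr_base_amp_uS: tuple[float, float] = (0.1, 0.4)
    eda_noise_uS: float = 0.01
    bateman_tau1_s: float = 2.0
    bateman_tau2_s: float = 0.75
    # BVP / heart rate
    hr_base_bpm: float = 72.0
    hr_subject_sd_bpm: float = 4.0
    hr_wander_bpm: float = 1.5
    bvp_noise: float = 0.02
    artifact_bursts_per_trip: float = 0.0
    artifact_amp: float = 4.0
    # stimulus response
    stimulus_effect: StimulusEffect = field(default_factory=StimulusEffect)
    effect_delay_s: float = 2.0
    effect_duration_s: float = 30.0
    report_location_sigma_m: float = 5.0
    stimulus_trigger_radius_m: float = 15.0
    # network & stimuli
    n_streets: int = 40
    street_length_m: float = 100.0
    stimulus_density_per_km: float = 2.5
    # sampling rates
    eda_rate_hz: float = 4.0
    bvp_rate_hz: float = 64.0
    acc_rate_hz: float = 50.0
    gps_interval_s: float = 3.0

    def __post_init__(self) -> None:
        eff = self.stimulus_effect
        if min(eff.extra_scr_amp_uS, eff.scr_burst_count, eff.hr_bump_bpm) < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if self.scr_base_rate_per_min < 0 or self.n_streets < 1:
            raise ValueError("invalid config")


@dataclass
class TripTruth:
    """Per-trip ground truth used by recovery tests."""

    trip_id: str
    passage_times: dict[int, float]      # stimulus index -> passage time (s)
    effect_windows: list[tuple[float, float]]
    pauses: list[tuple[float, float]]
    hr_times: np.ndarray                 # 4 Hz grid
    hr_true_bpm: np.ndarray
    scr_event_times: np.ndarray          # all injected SCR peaks' kernel onsets


@dataclass
class GroundTruth:
    """Study-level ground truth: stimuli and per-trip passage records."""

    stimulus_positions: np.ndarray       # (n, 2) planar meters
    stimulus_types: list[tuple[int, ...]]
    trips: dict[str, TripTruth] = field(default_factory=dict)


def bateman(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    """Peak-normalized biexponential SCR shape e^(-t/tau1) - e^(-t/tau2)."""
    if not tau1 > tau2 > 0:
        raise ValueError("require tau1 > tau2 > 0")
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau1) - np.exp(-np.maximum(t, 0) / tau2), 0.0)
    t_peak = tau1 * tau2 / (tau1 - tau2) * np.log(tau1 / tau2)
    peak = np.exp(-t_peak / tau1) - np.exp(-t_peak / tau2)
    return h / peak


# ---------------------------------------------------------------------------
# Street network and routes
# ---------------------------------------------------------------------------


def make_street_network(config: SynthConfig) -> list[LineString]:
    """Planar grid of street centerlines, ``n_streets`` edges of equal length.

    Edges are emitted in a serpentine order so that any prefix is connected;
    total length is exactly ``n_streets * street_length_m``.
    """
    n, L = config.n_streets, config.street_length_m
    k = 2
    while 2 * k * (k - 1) < n:
        k += 1
    # serpentine path through the k x k node grid first (always connected) ...
    edges: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for row in range(k):
        cols = range(k - 1) if row % 2 == 0 else range(k - 1, 0, -1)
        for c in cols:
            a, b = (c, row), (c + 1, row)
            edges.append((a, b) if row % 2 == 0 else (b, a))
        if row < k - 1:
            c_end = k - 1 if row % 2 == 0 else 0
            edges.append(((c_end, row), (c_end, row + 1)))
    # ... then every remaining grid edge (each touches the path)
    seen = {frozenset(e) for e in edges}
    for row in range(k):
        for c in range(k):
            for b in ((c + 1, row), (c, row + 1)):
                if b[0] < k and b[1] < k:
                    e = frozenset(((c, row), b))
                    if e not in seen:
                        seen.add(e)
                        edges.append(((c, row), b))
    edges = edges[:n]
    return [
        LineString([(a[0] * L, a[1] * L), (b[0] * L, b[1] * L)])
        for a, b in edges
    ]


def _street_graph(streets: list[LineString]) -> dict[tuple[float, float], list[tuple[float, float]]]:
    adj: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for ls in streets:
        a = tuple(np.round(ls.coords[0], 6))
        b = tuple(np.round(ls.coords[-1], 6))
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _random_route(
    streets: list[LineString], length_m: float, rng: np.random.Generator
) -> np.ndarray:
    """Random non-backtracking walk on the street graph, >= length_m long."""
    adj = _street_graph(streets)
    nodes = sorted(adj)
    cur = nodes[rng.integers(len(nodes))]
    prev = None
    pts = [cur]
    total = 0.0
    while total < length_m:
        nbrs = adj[cur]
        choices = [n for n in nbrs if n != prev] or nbrs
        nxt = choices[rng.integers(len(choices))]
        total += float(np.hypot(nxt[0] - cur[0], nxt[1] - cur[1]))
        pts.append(nxt)
        prev, cur = cur, nxt
    return np.asarray(pts, dtype=float)


def _place_stimuli(
    streets: list[LineString], config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    total_km = sum(ls.length for ls in streets) / 1000.0
    n = int(rng.poisson(config.stimulus_density_per_km * total_km))
    lengths = np.array([ls.length for ls in streets])
    probs = lengths / lengths.sum()
    positions = np.empty((n, 2))
    types: list[tuple[int, ...]] = []
    for i in range(n):
        ls = streets[rng.choice(len(streets), p=probs)]
        pt = ls.interpolate(rng.uniform(0, ls.length))
        positions[i] = (pt.x, pt.y)
        k = int(rng.integers(1, 4))
        types.append(tuple(sorted(rng.choice(np.arange(1, 15), size=k, replace=False).tolist())))
    return positions, types


# ---------------------------------------------------------------------------
# Per-trip signal synthesis
# ---------------------------------------------------------------------------


def _route_kinematics(
    route: np.ndarray, config: SynthConfig, pauses: list[tuple[float, float]], T: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative route arc-lengths and a walk-distance function s(t)."""
    seg = np.hypot(*(np.diff(route, axis=0).T))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    dt = 0.25
    t = np.arange(0.0, T + dt, dt)
    moving = np.ones_like(t)
    for a, b in pauses:
        moving[(t >= a) & (t < b)] = 0.0
    s = np.concatenate([[0.0], np.cumsum(moving[:-1]) * dt * config.walk_speed_mps])
    s = np.minimum(s, cum[-1])
    return cum, np.column_stack([t, s])


def _pos_along(route: np.ndarray, cum: np.ndarray, s: np.ndarray) -> np.ndarray:
    x = np.interp(s, cum, route[:, 0])
    y = np.interp(s, cum, route[:, 1])
    return np.column_stack([x, y])


def simulate_trip(
    subject_id: str,
    trip_id: str,
    route: np.ndarray,
    stimuli_pos: np.ndarray,
    stimuli_types: list[tuple[int, ...]],
    config: SynthConfig,
    rng: np.random.Generator,
    hr_base_bpm: float | None = None,
) -> tuple[WalkingTrip, list[StimulusReport], TripTruth]:
    """Simulate one trip along ``route`` past the study's stimuli.

    Returns the trip (channels already on the trip-relative clock), the
    subject's reports (true stimulus positions plus Gaussian location error)
    and the per-trip ground truth.
    """
    T = config.trip_duration_s
    eff = config.stimulus_effect
    if hr_base_bpm is None:
        hr_base_bpm = config.hr_base_bpm

    # optional mid-trip pause (zero motion, stationary GPS)
    pauses: list[tuple[float, float]] = []
    if rng.uniform() < config.pause_prob:
        dur = rng.uniform(*config.pause_duration_s)
        start = rng.uniform(0.15 * T, 0.85 * T - dur)
        pauses.append((start, start + dur))

    cum, ts_grid = _route_kinematics(route, config, pauses, T)
    grid_t, grid_s = ts_grid[:, 0], ts_grid[:, 1]

    # --- stimulus passages: nearest approach of the walked path ------------
    passage_times: dict[int, float] = {}
    if len(stimuli_pos):
        path_pos = _pos_along(route, cum, grid_s)
        for i, sp in enumerate(stimuli_pos):
            d = np.hypot(path_pos[:, 0] - sp[0], path_pos[:, 1] - sp[1])
            j = int(np.argmin(d))
            if d[j] <= config.stimulus_trigger_radius_m:
                passage_times[i] = float(grid_t[j])
    effect_windows = [
        (
            min(t0 + config.effect_delay_s, T),
            min(t0 + config.effect_delay_s + config.effect_duration_s, T),
        )
        for t0 in passage_times.values()
    ]

    def in_effect(t: np.ndarray) -> np.ndarray:
        m = np.zeros(len(t), dtype=bool)
        for a, b in effect_windows:
            m |= (t >= a) & (t < b)
        return m

    # --- EDA ----------------------------------------------------------------
    fs_e = config.eda_rate_hz
    te = np.arange(0.0, T, 1.0 / fs_e)
    drift = np.cumsum(rng.normal(0, 1, len(te)))
    if np.std(drift) > 0:
        from scipy.ndimage import gaussian_filter1d

        drift = gaussian_filter1d(drift, sigma=20 * fs_e)
        drift = drift / (np.std(drift) + 1e-12) * config.tonic_drift_uS
    tonic = config.tonic_base_uS + drift
    n_bg = rng.poisson(config.scr_base_rate_per_min * T / 60.0)
    ev_times = list(rng.uniform(0, T - 5.0, n_bg))
    ev_amps = list(rng.uniform(*config.scr_base_amp_uS, n_bg))
    for a, b in effect_windows:
        for _ in range(eff.scr_burst_count):
            ev_times.append(rng.uniform(a, max(a + 1e-3, b - 5.0)))
            ev_amps.append(eff.extra_scr_amp_uS * rng.uniform(0.9, 1.1))
    eda = tonic.copy()
    for t_ev, amp in zip(ev_times, ev_amps):
        tail = te >= t_ev
        eda[tail] += amp * bateman(te[tail] - t_ev, config.bateman_tau1_s, config.bateman_tau2_s)
    eda += rng.normal(0, config.eda_noise_uS, len(te))

    # --- ACC (gait) ----------------------------------------------------------
    fs_a = config.acc_rate_hz
    ta = np.arange(0.0, T, 1.0 / fs_a)
    slowdown = 1.0 + eff.stride_slowdown_frac * in_effect(ta)
    moving = np.ones(len(ta))
    for a, b in pauses:
        moving[(ta >= a) & (ta < b)] = 0.0
    f_inst = config.step_freq_hz / slowdown * moving
    phase = np.cumsum(f_inst) / fs_a
    A = config.step_amp_g * moving
    acc_z = (
        1.0
        + A * np.sin(2 * np.pi * phase)
        + 0.3 * A * np.sin(4 * np.pi * phase + 0.4)
        + rng.normal(0, config.acc_noise_g, len(ta))
    )
    acc_x = 0.3 * A * np.sin(2 * np.pi * phase + 1.1) + rng.normal(0, config.acc_noise_g, len(ta))
    acc_y = 0.2 * A * np.sin(2 * np.pi * phase + 2.3) + rng.normal(0, config.acc_noise_g, len(ta))

    # --- BVP ------------------------------------------------------------------
    fs_b = config.bvp_rate_hz
    tb = np.arange(0.0, T, 1.0 / fs_b)
    wander = np.sin(2 * np.pi * tb / 97.0 + rng.uniform(0, 2 * np.pi)) * config.hr_wander_bpm
    hr_true = hr_base_bpm + wander + eff.hr_bump_bpm * in_effect(tb)
    beat_phase = np.cumsum(hr_true / 60.0) / fs_b
    u = np.mod(beat_phase, 1.0)
    # raised-cosine systolic peak at u=0.15 (width 0.2) + small diastolic wave
    sys_peak = np.where(np.abs(u - 0.15) < 0.1, 0.5 * (1 + np.cos(np.pi * (u - 0.15) / 0.1)), 0.0)
    dia = 0.2 * np.where(np.abs(u - 0.55) < 0.15, 0.5 * (1 + np.cos(np.pi * (u - 0.55) / 0.15)), 0.0)
    bvp = sys_peak + dia - 0.25 + rng.normal(0, config.bvp_noise, len(tb))
    n_art = rng.poisson(config.artifact_bursts_per_trip)
    for _ in range(n_art):
        t_a = rng.uniform(0, T - 1.0)
        dur = rng.uniform(0.4, 1.0)
        m = (tb >= t_a) & (tb < t_a + dur)
        bvp[m] += rng.normal(0, config.artifact_amp, m.sum())

    # --- GPS ------------------------------------------------------------------
    tg = np.arange(0.0, T + 1e-9, config.gps_interval_s)
    sg = np.interp(tg, grid_t, grid_s)
    gps = _pos_along(route, cum, sg)

    channels = {
        "eda": SignalChannel("eda", fs_e, 0.0, eda),
        "bvp": SignalChannel("bvp", fs_b, 0.0, bvp),
        "acc_x": SignalChannel("acc_x", fs_a, 0.0, acc_x),
        "acc_y": SignalChannel("acc_y", fs_a, 0.0, acc_y),
        "acc_z": SignalChannel("acc_z", fs_a, 0.0, acc_z),
    }
    trip = WalkingTrip(trip_id, subject_id, channels, GeoTrack(tg, gps))

    reports = [
        StimulusReport(
            trip_id=trip_id,
            position=(
                float(stimuli_pos[i][0] + rng.normal(0, config.report_location_sigma_m)),
                float(stimuli_pos[i][1] + rng.normal(0, config.report_location_sigma_m)),
            ),
            stimulus_types=stimuli_types[i],
            report_time=t0,
        )
        for i, t0 in passage_times.items()
    ]
    hr_grid = np.arange(0.0, T, 0.25)
    truth = TripTruth(
        trip_id=trip_id,
        passage_times=passage_times,
        effect_windows=effect_windows,
        pauses=pauses,
        hr_times=hr_grid,
        hr_true_bpm=np.interp(hr_grid, tb, hr_true),
        scr_event_times=np.asarray(sorted(ev_times)),
    )
    return trip, reports, truth


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------


def simulate_study(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[WalkingTrip], list[StimulusReport], GroundTruth, list[LineString]]:
    """Simulate the full study: network, stimuli, subjects, trips, reports.

    With ``out_dir`` set, all artifacts are written in the formats
    :mod:`walkstress.io_formats` reads, plus ``ground_truth.json``.
    """
    root = np.random.SeedSequence(config.seed)
    ss_net, ss_stim, ss_subj = root.spawn(3)
    rng_net = np.random.default_rng(ss_net)
    streets = make_street_network(config)
    positions, types = _place_stimuli(streets, config, np.random.default_rng(ss_stim))
    gt = GroundTruth(stimulus_positions=positions, stimulus_types=types)

    trips: list[WalkingTrip] = []
    reports: list[StimulusReport] = []
    lo, hi = config.trips_per_subject
    subj_streams = ss_subj.spawn(config.n_subjects)
    route_len = config.walk_speed_mps * config.trip_duration_s + 2 * config.street_length_m
    for si, ss in enumerate(subj_streams):
        rng_s = np.random.default_rng(ss)
        subject_id = f"S{si:03d}"
        hr_base = config.hr_base_bpm + rng_s.normal(0, config.hr_subject_sd_bpm)
        n_trips = int(rng_s.integers(lo, hi + 1))
        for ti in range(n_trips):
            trip_id = f"{subject_id}_T{ti:02d}"
            route = _random_route(streets, route_len, rng_s)
            trip, reps, truth = simulate_trip(
                subject_id, trip_id, route, positions, types, config, rng_s, hr_base
            )
            trips.append(trip)
            reports.extend(reps)
            gt.trips[trip_id] = truth

    if out_dir is not None:
        _write_study(Path(out_dir), config, trips, reports, gt, streets)
    return trips, reports, gt, streets


def _write_study(
    out: Path,
    config: SynthConfig,
    trips: list[WalkingTrip],
    reports: list[StimulusReport],
    gt: GroundTruth,
    streets: list[LineString],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_streets_geojson(out / "streets.geojson", streets, crs="local_m")
    write_reports_csv(out / "reports.csv", reports)
    for trip in trips:
        tdir = out / "trips" / trip.trip_id
        tdir.mkdir(parents=True, exist_ok=True)
        write_e4_channel(tdir / "EDA.csv", trip.channel("eda"))
        write_e4_channel(tdir / "BVP.csv", trip.channel("bvp"))
        write_e4_channel(
            tdir / "ACC.csv",
            [trip.channel("acc_x"), trip.channel("acc_y"), trip.channel("acc_z")],
        )
        write_track_csv(tdir / "track.csv", trip.track)
    gt_json = {
        "config": _config_to_json(config),
        "stimulus_positions": gt.stimulus_positions.tolist(),
        "stimulus_types": [list(t) for t in gt.stimulus_types],
        "trips": {
            tid: {
                "passage_times": {str(k): v for k, v in tt.passage_times.items()},
                "effect_windows": tt.effect_windows,
                "pauses": tt.pauses,
                "mean_hr_bpm": float(np.mean(tt.hr_true_bpm)),
            }
            for tid, tt in gt.trips.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt_json, fh, indent=1)


def _config_to_json(config: SynthConfig) -> dict:
    d = asdict(config)
    return d
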