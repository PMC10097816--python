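"""Shared fixtures: small synthetic signals and studies built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from walkstress.io_formats import SignalChannel
from walkstress.synth import SynthConfig, bateman


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_gait_acc(
    duration_s: float = 120.0,
    fs: float = 50.0,
    step_freq_hz: float = 2.0,
    amp_g: float = 0.8,
    noise_g: float = 0.0,
    pauses: list[tuple[float, float]] | None = None,
    seed: int = 0,
) -> dict[str, SignalChannel]:
    """Three-axis walking acceleration with optional zero-motion pauses."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / fs)
    moving = np.ones_like(t)
    for a, b in pauses or []:
        moving[(t >= a) & (t < b)] = 0.0
    phase = np.cumsum(step_freq_hz * moving) / fs
    A = amp_g * moving
    z = 1.0 + A * np.sin(2 * np.pi * phase) + rng.normal(0, noise_g, len(t))
    x = 0.3 * A * np.sin(2 * np.pi * phase + 1.1) + rng.normal(0, noise_g, len(t))
    y = 0.2 * A * np.sin(2 * np.pi * phase + 2.3) + rng.normal(0, noise_g, len(t))
    return {
        "acc_x": SignalChannel("acc_x", fs, 0.0, x),
        "acc_y": SignalChannel("acc_y", fs, 0.0, y),
        "acc_z": SignalChannel("acc_z", fs, 0.0, z),
    }


def make_bvp(
    duration_s: float = 120.0,
    fs: float = 64.0,
    hr_bpm: float | np.ndarray = 72.0,
    noise: float = 0.0,
    seed: int = 0,
) -> SignalChannel:
    """Pulse wave with a raised-cosine systolic peak per beat."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / fs)
    hr = np.broadcast_to(np.asarray(hr_bpm, float), t.shape)
    phase = np.cumsum(hr / 60.0) / fs
    u = np.mod(phase, 1.0)
    sys_peak = np.where(np.abs(u - 0.15) < 0.1, 0.5 * (1 + np.cos(np.pi * (u - 0.15) / 0.1)), 0.0)
    dia = 0.2 * np.where(np.abs(u - 0.55) < 0.15, 0.5 * (1 + np.cos(np.pi * (u - 0.55) / 0.15)), 0.0)
    v = sys_peak + dia - 0.25 + rng.normal(0, noise, len(t))
    return SignalChannel("bvp", fs, 0.0, v)


def make_eda(
    duration_s: float = 300.0,
    fs: float = 4.0,
    tonic_uS: float = 2.0,
    scr_times: list[float] | None = None,
    scr_amps: list[float] | None = None,
    noise_uS: float = 0.0,
    seed: int = 0,
) -> SignalChannel:
    """Tonic level plus Bateman-shaped SCRs at given onsets/amplitudes."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / fs)
    v = np.full_like(t, tonic_uS)
    for t0, a in zip(scr_times or [], scr_amps or []):
        tail = t >= t0
        v[tail] += a * bateman(t[tail] - t0, 2.0, 0.75)
    v += rng.normal(0, noise_uS, len(t))
    return SignalChannel("eda", fs, 0.0, v)


@pytest.fixture(scope="session")
def tiny_study():
    """A 4-subject strong-effect study shared by integration-level tests."""
    from walkstress.synth import simulate_study

    cfg = SynthConfig(
        seed=42,
        n_subjects=4,
        trips_per_subject=(3, 4),
        trip_duration_s=240.0,
        n_streets=12,
        stimulus_density_per_km=6.0,
    )
    trips, reports, gt, streets = simulate_study(cfg)
    return {"config": cfg, "trips": trips, "reports": reports, "gt": gt, "streets": streets}
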