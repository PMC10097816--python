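"""Per-channel cleaning of wearable walking-trip signals.

EDA is smoothed with a short FIR Bateman kernel and screened with three
rules (mean below 0.01 µS, zero SCR frequency, SCR frequency over
25 counts/min). The triaxial accelerometer is low-passed with a 4 Hz
zero-phase Butterworth filter and scanned for non-walking interruptions
with a short-time Fourier transform (3 s window): contiguous stretches
whose gait-band spectral amplitude stays below 0.5 for at least 15 s are
flagged and excluded downstream. BVP is band-pass filtered around the
cardiac band, denoised with a discrete wavelet transform, and converted
to a beat-to-beat heart-rate series smoothed with a moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .io_formats import SignalChannel

__all__ = [
    "QualityDecision",
    "IntervalSet",
    "HeartRateSeries",
    "bateman_kernel",
    "smooth_eda",
    "screen_eda",
    "filter_imu",
    "detect_interruptions",
    "clean_bvp",
    "estimate_heart_rate",
]

#: Screening thresholds (published rules).
MEAN_EDA_MIN_US = 0.01
SCR_RATE_MAX_PER_MIN = 25.0

#: Interruption-detection constants.
STFT_WINDOW_S = 3.0
SPECTRAL_AMP_THRESHOLD = 0.5
MIN_INTERRUPTION_S = 15.0
GAIT_BAND_HZ = (0.5, 3.0)

#: Heart-rate plausibility band (bpm) after refinement.
HR_MIN_BPM, HR_MAX_BPM = 30.0, 220.0
MIN_IBI_S = 0.27  # ~220 bpm


@dataclass(frozen=True)
class QualityDecision:
    """Outcome of the EDA usability screen; usable iff no reasons."""

    reasons: tuple[str, ...]

    @property
    def usable(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint, sorted half-open [start, end) intervals on the trip clock."""

    intervals: tuple[tuple[float, float], ...] = ()

    @staticmethod
    def from_raw(raw: list[tuple[float, float]], merge_gap_s: float = 0.0) -> "IntervalSet":
        if not raw:
            return IntervalSet()
        raw = sorted((float(a), float(b)) for a, b in raw if b > a)
        merged = [list(raw[0])]
        for a, b in raw[1:]:
            if a <= merged[-1][1] + merge_gap_s:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return IntervalSet(tuple((a, b) for a, b in merged))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration_s(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any interval."""
        t = np.asarray(t, dtype=float)
        m = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            m |= (t >= a) & (t < b)
        return m

    def overlap_s(self, a: float, b: float) -> float:
        """Total overlap of [a, b) with the interval set."""
        return sum(max(0.0, min(b, ib) - max(a, ia)) for ia, ib in self.intervals)


@dataclass(frozen=True)
class HeartRateSeries:
    """Beat-anchored heart-rate series (bpm at inter-beat midpoints)."""

    timestamps: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, float))
        object.__setattr__(self, "bpm", np.asarray(self.bpm, float))

    def __len__(self) -> int:
        return len(self.bpm)

    @property
    def mean_bpm(self) -> float:
        return float(np.mean(self.bpm)) if len(self.bpm) else float("nan")


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------


def bateman_kernel(
    tau1_s: float = 2.0,
    tau2_s: float = 0.75,
    rate_hz: float = 4.0,
    length_samples: int = 12,
) -> np.ndarray:
    """Unit-sum FIR Bateman kernel h[k] = e^(-k/(tau1 fs)) - e^(-k/(tau2 fs)).

    The biexponential is the standard sudomotor impulse-response shape; at
    12 samples and 4 Hz it spans 3 s. h[0] = 0 before normalization.
    """
    if not tau1_s > tau2_s > 0:
        raise ValueError("require tau1_s > tau2_s > 0")
    k = np.arange(length_samples, dtype=float)
    h = np.exp(-k / (tau1_s * rate_hz)) - np.exp(-k / (tau2_s * rate_hz))
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate kernel (increase length or rate)")
    return h / s


def smooth_eda(
    eda: SignalChannel,
    tau1_s: float = 2.0,
    tau2_s: float = 0.75,
    length_samples: int = 12,
) -> SignalChannel:
    """Smooth EDA by convolution with the 12-sample unit-sum Bateman kernel.

    Reflect padding keeps output length equal to input length and preserves
    the mean of stationary inputs.
    """
    if eda.kind != "eda":
        raise ValueError("smooth_eda expects an EDA channel")
    n = len(eda)
    if n < length_samples:
        raise ValueError(f"channel too short to smooth ({n} < {length_samples} samples)")
    h = bateman_kernel(tau1_s, tau2_s, eda.sampling_rate_hz, length_samples)
    pad = length_samples - 1
    # causal convolution with left reflect padding: a response's onset stays
    # at its sample and an impulse reproduces the kernel in place
    x = np.concatenate([eda.values[pad:0:-1], eda.values])
    y = np.convolve(x, h, mode="valid")
    return SignalChannel("eda", eda.sampling_rate_hz, eda.start_time, y)


def screen_eda(eda: SignalChannel, scr_events: list) -> QualityDecision:
    """Apply the three EDA usability rules.

    Rejects when mean EDA < 0.01 µS, when no SCR was detected, or when the
    SCR rate exceeds 25 counts per minute.
    """
    reasons: list[str] = []
    if float(np.mean(eda.values)) < MEAN_EDA_MIN_US:
        reasons.append("low_mean_eda")
    n_scr = len(scr_events)
    if n_scr == 0:
        reasons.append("zero_scr_frequency")
    minutes = eda.duration_s / 60.0
    if minutes > 0 and n_scr / minutes > SCR_RATE_MAX_PER_MIN:
        reasons.append("excess_scr_frequency")
    return QualityDecision(tuple(reasons))


# ---------------------------------------------------------------------------
# IMU
# ---------------------------------------------------------------------------


def filter_imu(acc: SignalChannel, cutoff_hz: float = 4.0, order: int = 4) -> SignalChannel:
    """Zero-phase Butterworth low-pass (4 Hz) on one accelerometer axis."""
    if not acc.kind.startswith("acc"):
        raise ValueError("filter_imu expects an accelerometer channel")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=acc.sampling_rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, acc.values)
    return SignalChannel(acc.kind, acc.sampling_rate_hz, acc.start_time, y)


def detect_interruptions(
    acc_x: SignalChannel,
    acc_y: SignalChannel,
    acc_z: SignalChannel,
    window_s: float = STFT_WINDOW_S,
    amp_threshold: float = SPECTRAL_AMP_THRESHOLD,
    min_duration_s: float = MIN_INTERRUPTION_S,
    gait_band_hz: tuple[float, float] = GAIT_BAND_HZ,
) -> IntervalSet:
    """Flag non-walking / unusable stretches from the acceleration magnitude.

    Steps: (1) magnitude sqrt(x^2+y^2+z^2), mean-removed; (2) STFT with a
    3 s Hann window, 50 % overlap; (3) frames whose one-sided gait-band
    (0.5-3 Hz) amplitude stays below 0.5 (input in g) for a contiguous run
    of at least 15 s become an interval; (4) intervals separated by less
    than one hop are merged.
    """
    fs = acc_x.sampling_rate_hz
    if not (fs == acc_y.sampling_rate_hz == acc_z.sampling_rate_hz):
        raise ValueError("accelerometer axes must share a sampling rate")
    n = min(len(acc_x), len(acc_y), len(acc_z))
    mag = np.sqrt(
        acc_x.values[:n] ** 2 + acc_y.values[:n] ** 2 + acc_z.values[:n] ** 2
    )
    mag = mag - np.mean(mag)  # remove gravity offset
    nper = int(round(window_s * fs))
    hop = nper // 2
    win = signal.get_window("hann", nper)
    sft = signal.ShortTimeFFT(win, hop=hop, fs=fs, scale_to="magnitude")
    S = np.abs(sft.stft(mag))
    # one-sided amplitude: a sinusoid of amplitude A in-band reads ~A
    S *= 2.0
    freqs = sft.f
    band = (freqs >= gait_band_hz[0]) & (freqs <= gait_band_hz[1])
    frame_amp = S[band].max(axis=0)
    t_frames = sft.t(n)
    hop_s = hop / fs
    below = frame_amp < amp_threshold
    T = n / fs

    raw: list[tuple[float, float]] = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j + 1 < len(below) and below[j + 1]:
                j += 1
            a = max(0.0, t_frames[i] - hop_s / 2)
            b = min(T, t_frames[j] + hop_s / 2)
            if b - a >= min_duration_s:
                raw.append((a, b))
            i = j + 1
        else:
            i += 1
    return IntervalSet.from_raw(raw, merge_gap_s=hop_s)


# ---------------------------------------------------------------------------
# BVP
# ---------------------------------------------------------------------------


def clean_bvp(
    bvp: SignalChannel,
    passband_hz: tuple[float, float] = (0.6, 4.0),
    order: int = 2,
    wavelet: str = "db4",
    dwt_levels: int = 5,
) -> SignalChannel:
    """Band-pass BVP around the cardiac band, then wavelet-denoise.

    The pass band 0.6-4 Hz covers 36-240 bpm (transition edges near 0.4 and
    8 Hz); the discrete wavelet step (db4, 5 levels, soft universal
    threshold on detail coefficients) suppresses impulsive motion-artifact
    bursts. Output length equals input length.
    """
    if bvp.kind != "bvp":
        raise ValueError("clean_bvp expects a BVP channel")
    sos = signal.butter(
        order, passband_hz, btype="bandpass", fs=bvp.sampling_rate_hz, output="sos"
    )
    y = signal.sosfiltfilt(sos, bvp.values)
    n = len(y)
    coeffs = pywt.wavedec(y, wavelet, level=dwt_levels)
    # noise scale from the finest detail band (robust MAD estimate)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
    y = pywt.waverec(coeffs, wavelet)[:n]
    return SignalChannel("bvp", bvp.sampling_rate_hz, bvp.start_time, y)


def detect_beats(bvp: SignalChannel) -> np.ndarray:
    """Systolic-peak times (s) with a 0.27 s minimum inter-beat interval.

    Two stages: candidate maxima at the minimum spacing, then a height
    gate at half the 90th-percentile peak height, which rejects diastolic
    secondary peaks without tracking the pulse amplitude explicitly.
    """
    x = bvp.values
    sd = np.std(x)
    if sd <= 0:
        return np.array([])
    peaks, _ = signal.find_peaks(
        x, distance=max(1, int(MIN_IBI_S * bvp.sampling_rate_hz)), prominence=0.1 * sd
    )
    if len(peaks) == 0:
        return np.array([])
    h = x[peaks]
    peaks = peaks[h > 0.5 * np.percentile(h, 90)]
    return bvp.start_time + peaks / bvp.sampling_rate_hz


def estimate_heart_rate(
    bvp_clean: SignalChannel, smooth_beats: int = 5
) -> HeartRateSeries:
    """Beat-to-beat heart rate from cleaned BVP.

    Instantaneous bpm = 60/IBI at inter-beat midpoints; implausible beats
    (outside 30-220 bpm) are dropped; a centered moving average over 5
    beats refines the series. With fewer than 3 detected beats an empty
    series is returned with a warning.
    """
    beat_times = detect_beats(bvp_clean)
    if len(beat_times) < 3:
        warnings.warn("fewer than 3 beats detected; returning empty heart-rate series")
        return HeartRateSeries(np.array([]), np.array([]))
    ibi = np.diff(beat_times)
    bpm = 60.0 / ibi
    mid = (beat_times[:-1] + beat_times[1:]) / 2
    ok = (bpm >= HR_MIN_BPM) & (bpm <= HR_MAX_BPM)
    bpm, mid = bpm[ok], mid[ok]
    if len(bpm) == 0:
        warnings.warn("no plausible beats after range filtering")
        return HeartRateSeries(np.array([]), np.array([]))
    if smooth_beats > 1 and len(bpm) > 1:
        k = smooth_beats
        kernel = np.ones(k)
        num = np.convolve(bpm, kernel, mode="same")
        den = np.convolve(np.ones_like(bpm), kernel, mode="same")
        bpm = num / den
    return HeartRateSeries(mid, bpm)
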