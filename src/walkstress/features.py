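"""Feature extraction: raw biosignal features and saliency (PSC) features.

Six feature families are produced per trip and geocoded onto the GPS
track: skin conductance level (SCL), SCR amplitude and frequency, stride
time, mean heart rate, and the three physiological saliency cues (EDA
PSC, IMU PSC, BVP PSC). Saliency is computed by first splitting a series
into variable-length segments with classical bottom-up merging, then
scoring each segment's contrast (distance-weighted absolute difference
of segment means) against all other segments.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io_formats import GeoTrack, SignalChannel
from .preprocess import IntervalSet

__all__ = [
    "ScrEvent",
    "SegmentBoundaries",
    "FeatureSeries",
    "FEATURE_NAMES",
    "detect_scrs",
    "compute_stride_time",
    "bottomup_segment",
    "compute_psc",
    "geocode_features",
]

FEATURE_NAMES = (
    "scl",
    "scr_amplitude",
    "scr_frequency",
    "stride_time",
    "mean_hr",
    "eda_psc",
    "imu_psc",
    "bvp_psc",
)

#: Minimum trough-to-peak amplitude for an SCR to be counted (µS).
MIN_SCR_AMP_US = 0.01
#: Rolling-median window for the tonic (SCL) estimate (s).
TONIC_WINDOW_S = 4.0


@dataclass(frozen=True)
class ScrEvent:
    """One skin conductance response: onset, peak, trough-to-peak amplitude."""

    onset_s: float
    peak_s: float
    amplitude_uS: float

    def __post_init__(self) -> None:
        if not self.peak_s > self.onset_s:
            raise ValueError("peak must follow onset")
        if self.amplitude_uS < MIN_SCR_AMP_US:
            raise ValueError("amplitude below minimum SCR amplitude")


@dataclass(frozen=True)
class SegmentBoundaries:
    """Variable-length segmentation of a series.

    ``boundaries`` are strictly increasing indices from 0 to len(series);
    segment i covers ``[boundaries[i], boundaries[i+1])`` and its
    representative attribute is the series mean over that span.
    """

    boundaries: np.ndarray
    attributes: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        a = np.asarray(self.attributes, dtype=float)
        if b[0] != 0 or len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must strictly increase from 0")
        if len(a) != len(b) - 1:
            raise ValueError("one attribute per segment required")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "attributes", a)

    @property
    def n_segments(self) -> int:
        return len(self.attributes)


@dataclass(frozen=True)
class FeatureSeries:
    """A geocoded time series of one extracted feature."""

    feature: str
    timestamps: np.ndarray
    values: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.positions is not None:
            object.__setattr__(self, "positions", np.asarray(self.positions, float))

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# EDA features
# ---------------------------------------------------------------------------


def detect_scrs(
    eda_smoothed: SignalChannel, min_amp_uS: float = MIN_SCR_AMP_US
) -> tuple[FeatureSeries, list[ScrEvent]]:
    """Tonic/phasic split and trough-to-peak SCR detection.

    The tonic (SCL) estimate is a 4 s rolling median of the smoothed EDA;
    the phasic residual is scanned for peaks, each paired with the
    preceding local minimum (the onset). The event amplitude is the
    conductance rise peak - onset measured on the smoothed signal itself
    (the rolling median damps but does not remove a response, so the
    residual would understate it). Events below 0.01 µS are discarded.
    """
    fs = eda_smoothed.sampling_rate_hz
    x = eda_smoothed.values
    win = max(3, int(round(TONIC_WINDOW_S * fs)) | 1)  # odd size
    tonic = ndimage.median_filter(x, size=win, mode="nearest")
    phasic = x - tonic
    t = eda_smoothed.times()
    scl = FeatureSeries("scl", t, tonic)

    events: list[ScrEvent] = []
    peaks, _ = signal.find_peaks(phasic, prominence=min_amp_uS)
    prev_peak = 0
    max_rise = int(round(10.0 * fs))  # onset search horizon before the peak
    for p in peaks:
        # onset = conductance trough preceding the peak: walk back keeping
        # the running minimum, stop once values climb clearly above it
        # (that is the previous response's decay)
        tol = min_amp_uS
        onset = p
        run_min = x[p]
        i = p
        lo = max(prev_peak, p - max_rise)
        while i > lo:
            i -= 1
            if x[i] < run_min:
                run_min = x[i]
                onset = i
            elif x[i] > run_min + tol:
                break
        amp = float(x[p] - x[onset])
        if amp >= min_amp_uS and onset < p:
            events.append(
                ScrEvent(onset_s=float(t[onset]), peak_s=float(t[p]), amplitude_uS=amp)
            )
            prev_peak = p
    return scl, events


def scr_feature_series(
    events: list[ScrEvent],
    duration_s: float,
    rate_window_s: float = 60.0,
    grid_step_s: float = 1.0,
) -> tuple[FeatureSeries, FeatureSeries]:
    """SCR amplitude (per event) and frequency (counts/min, rolling) series."""
    peak_times = np.array([e.peak_s for e in events])
    amps = np.array([e.amplitude_uS for e in events])
    amp_series = FeatureSeries("scr_amplitude", peak_times, amps)
    grid = np.arange(0.0, duration_s, grid_step_s)
    half = rate_window_s / 2.0
    lo = np.searchsorted(peak_times, grid - half)
    hi = np.searchsorted(peak_times, grid + half)
    # effective centered window, truncated at trip edges
    w = np.minimum(grid + half, duration_s) - np.maximum(grid - half, 0.0)
    rate = (hi - lo) / np.maximum(w, 1e-9) * 60.0
    return amp_series, FeatureSeries("scr_frequency", grid, rate)


# ---------------------------------------------------------------------------
# Gait
# ---------------------------------------------------------------------------


def compute_stride_time(
    acc_channels: dict[str, SignalChannel],
    interruptions: IntervalSet,
    min_step_interval_s: float = 0.3,
) -> FeatureSeries:
    """Stride time (two successive steps) from heel-strike peaks.

    Peaks are detected on the largest-variance (vertical) axis; stride time
    is the spacing between alternate peaks, emitted at the stride midpoint.
    Strides touching an interruption interval are dropped; walking bouts
    with fewer than 4 peaks contribute nothing.
    """
    axes = [acc_channels[k] for k in ("acc_x", "acc_y", "acc_z") if k in acc_channels]
    if not axes:
        raise ValueError("no accelerometer channels")
    vert = max(axes, key=lambda c: float(np.var(c.values)))
    fs = vert.sampling_rate_hz
    x = vert.values - np.mean(vert.values)
    prom = 0.5 * np.std(x)
    peaks, _ = signal.find_peaks(
        x, distance=max(1, int(min_step_interval_s * fs)), prominence=prom
    )
    peak_t = vert.start_time + peaks / fs
    # split peaks into walking bouts at interruption boundaries
    bout_edges = np.searchsorted(peak_t, [b for iv in interruptions for b in iv])
    bouts = np.split(np.arange(len(peak_t)), bout_edges)
    times, values = [], []
    in_interrupt = interruptions.contains(peak_t)
    for bout in bouts:
        bout = bout[~in_interrupt[bout]]
        if len(bout) < 4:
            continue
        bt = peak_t[bout]
        stride = bt[2:] - bt[:-2]
        mids = (bt[2:] + bt[:-2]) / 2.0
        times.append(mids)
        values.append(stride)
    if not times:
        return FeatureSeries("stride_time", np.array([]), np.array([]))
    t = np.concatenate(times)
    v = np.concatenate(values)
    order = np.argsort(t)
    return FeatureSeries("stride_time", t[order], v[order])


# ---------------------------------------------------------------------------
# Saliency: bottom-up segmentation and PSC
# ---------------------------------------------------------------------------


def bottomup_segment(series: np.ndarray, max_merge_cost: float) -> SegmentBoundaries:
    """Classical bottom-up merging with a squared-error cost cap.

    Starts from 2-sample segments and repeatedly merges the adjacent pair
    with the smallest increase in total within-segment squared error, until
    the cheapest merge would exceed ``max_merge_cost``. With an infinite
    cap the whole series collapses to one segment.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have length >= 2")
    # segment sufficient statistics: start, end, sum, sum of squares
    starts = list(range(0, n, 2))
    segs: list[list[float] | None] = []
    for s in starts:
        e = min(s + 2, n)
        v = x[s:e]
        segs.append([float(s), float(e), float(v.sum()), float((v**2).sum())])

    def sse(seg: list[float]) -> float:
        npts = seg[1] - seg[0]
        return seg[3] - seg[2] ** 2 / npts

    def merge_cost(a: list[float], b: list[float]) -> float:
        merged = [a[0], b[1], a[2] + b[2], a[3] + b[3]]
        return sse(merged) - sse(a) - sse(b)

    # doubly linked list over segment slots + lazy heap of candidate merges
    nseg = len(segs)
    nxt = list(range(1, nseg)) + [-1]
    prv = [-1] + list(range(nseg - 1))
    alive = [True] * nseg
    version = [0] * nseg
    heap: list[tuple[float, int, int, int, int]] = []
    for i in range(nseg - 1):
        heapq.heappush(heap, (merge_cost(segs[i], segs[i + 1]), i, i + 1, 0, 0))

    while heap:
        cost, i, j, vi, vj = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or version[i] != vi or version[j] != vj:
            continue
        if cost > max_merge_cost:
            break
        a, b = segs[i], segs[j]
        segs[i] = [a[0], b[1], a[2] + b[2], a[3] + b[3]]
        version[i] += 1
        alive[j] = False
        nxt[i] = nxt[j]
        if nxt[j] != -1:
            prv[nxt[j]] = i
        if prv[i] != -1:
            p = prv[i]
            heapq.heappush(heap, (merge_cost(segs[p], segs[i]), p, i, version[p], version[i]))
        if nxt[i] != -1:
            q = nxt[i]
            heapq.heappush(heap, (merge_cost(segs[i], segs[q]), i, q, version[i], version[q]))

    bounds = [0]
    attrs = []
    k = 0
    while k != -1:
        if alive[k]:
            s, e = int(segs[k][0]), int(segs[k][1])
            bounds.append(e)
            attrs.append(segs[k][2] / (e - s))
        k = nxt[k] if alive[k] else nxt[k]
    return SegmentBoundaries(np.asarray(bounds), np.asarray(attrs))


def compute_psc(
    series: np.ndarray,
    boundaries: SegmentBoundaries,
    distance_weighted: bool = True,
) -> np.ndarray:
    """Per-sample physiological saliency cue from segment contrasts.

    For segment i with attribute a_i, PSC(i) = sum_j w_ij |a_i - a_j| with
    inverse-distance weights w_ij normalized over j != i (distances between
    segment centers, in samples). Every sample inherits its segment's PSC.
    With the unweighted variant all w_ij are equal. A single segment yields
    an all-zero PSC.
    """
    n = len(series)
    b = boundaries.boundaries
    if b[-1] != n:
        raise ValueError("boundaries do not cover the series")
    a = boundaries.attributes
    S = len(a)
    psc_seg = np.zeros(S)
    if S > 1:
        centers = (b[:-1] + b[1:] - 1) / 2.0
        diff = np.abs(a[:, None] - a[None, :])
        if distance_weighted:
            d = np.abs(centers[:, None] - centers[None, :])
            with np.errstate(divide="ignore"):
                w = 1.0 / d
            np.fill_diagonal(w, 0.0)
            w = w / w.sum(axis=1, keepdims=True)
        else:
            w = np.full((S, S), 1.0 / (S - 1))
            np.fill_diagonal(w, 0.0)
        psc_seg = (w * diff).sum(axis=1)
    out = np.empty(n)
    for i in range(S):
        out[b[i] : b[i + 1]] = psc_seg[i]
    return out


def psc_series(
    base: FeatureSeries,
    feature_name: str,
    max_merge_cost: float | None = None,
    distance_weighted: bool = True,
) -> FeatureSeries:
    """Bottom-up segment a feature series and attach per-sample PSC values.

    Default merge-cost cap is twice the series variance (scale-free
    stopping rule for the non-fixed-length segmentation).
    """
    v = base.values
    if len(v) < 2:
        return FeatureSeries(feature_name, base.timestamps, np.zeros(len(v)))
    if max_merge_cost is None:
        max_merge_cost = 2.0 * float(np.var(v))
    seg = bottomup_segment(v, max_merge_cost)
    return FeatureSeries(feature_name, base.timestamps, compute_psc(v, seg))


# ---------------------------------------------------------------------------
# Geocoding
# ---------------------------------------------------------------------------


def geocode_features(series: FeatureSeries, track: GeoTrack) -> FeatureSeries:
    """Attach linearly interpolated track positions to each feature sample.

    Samples outside the track's time span are dropped; the caller can
    compare input and output lengths to count them.
    """
    t = series.timestamps
    inside = (t >= track.start_time) & (t <= track.end_time)
    t_in = t[inside]
    pos = track.positions_at(t_in)
    return FeatureSeries(series.feature, t_in, series.values[inside], pos)
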