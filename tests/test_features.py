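"""SCR detection, stride time, bottom-up segmentation, PSC, geocoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkstress import features as ft
from walkstress import preprocess as pp
from walkstress.io_formats import GeoTrack, SignalChannel
from walkstress.preprocess import IntervalSet

from conftest import make_eda, make_gait_acc


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_psc(series: np.ndarray, boundaries: np.ndarray, weighted: bool = True) -> np.ndarray:
    """Direct, loop-based evaluation of the distance-weighted contrast sum."""
    b = boundaries
    S = len(b) - 1
    attrs = [np.mean(series[b[i] : b[i + 1]]) for i in range(S)]
    centers = [(b[i] + b[i + 1] - 1) / 2.0 for i in range(S)]
    psc = np.zeros(S)
    for i in range(S):
        if S == 1:
            break
        if weighted:
            inv = [1.0 / abs(centers[i] - centers[j]) for j in range(S) if j != i]
            wsum = sum(inv)
            total = 0.0
            k = 0
            for j in range(S):
                if j == i:
                    continue
                total += (inv[k] / wsum) * abs(attrs[i] - attrs[j])
                k += 1
            psc[i] = total
        else:
            psc[i] = np.mean([abs(attrs[i] - attrs[j]) for j in range(S) if j != i])
    out = np.empty(len(series))
    for i in range(S):
        out[b[i] : b[i + 1]] = psc[i]
    return out


def exhaustive_single_boundary(series: np.ndarray) -> int:
    """Best single split by total squared error, checked by enumeration."""
    best, best_sse = 1, np.inf
    for cut in range(1, len(series)):
        left, right = series[:cut], series[cut:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, cut
    return best


# ---------------------------------------------------------------------------
# SCR detection
# ---------------------------------------------------------------------------


def test_detect_scrs_constant_signal():
    ch = pp.smooth_eda(SignalChannel("eda", 4.0, 0.0, np.full(480, 2.0)))
    scl, events = ft.detect_scrs(ch)
    assert events == []
    assert np.allclose(scl.values, 2.0)


def test_detect_scrs_single_injected_event():
    eda = make_eda(duration_s=120.0, scr_times=[60.0], scr_amps=[0.5])
    _, events = ft.detect_scrs(pp.smooth_eda(eda))
    assert len(events) == 1
    ev = events[0]
    # smoothing attenuates the 0.5 µS peak slightly
    assert 0.4 <= ev.amplitude_uS <= 0.5
    assert ev.onset_s == pytest.approx(60.0, abs=0.5)
    assert ev.peak_s > ev.onset_s


def test_detect_scrs_two_events_onsets():
    eda = make_eda(duration_s=120.0, scr_times=[50.0, 60.0], scr_amps=[0.5, 0.5])
    _, events = ft.detect_scrs(pp.smooth_eda(eda))
    assert len(events) == 2
    assert events[0].onset_s == pytest.approx(50.0, abs=0.5)
    assert events[1].onset_s == pytest.approx(60.0, abs=0.5)


def test_scr_count_single_source_of_truth():
    # the same event list feeds screening and the frequency series
    eda = make_eda(duration_s=600.0, scr_times=list(range(30, 570, 60)), scr_amps=[0.3] * 9)
    sm = pp.smooth_eda(eda)
    _, events = ft.detect_scrs(sm)
    q = pp.screen_eda(sm, events)
    assert q.usable
    _, freq = ft.scr_feature_series(events, 600.0)
    # total counts recovered from the rate series integral
    approx_total = np.mean(freq.values) * 10.0
    assert approx_total == pytest.approx(len(events), rel=0.2)


# ---------------------------------------------------------------------------
# Stride time
# ---------------------------------------------------------------------------


def test_stride_time_two_hz_gait():
    acc = {k: pp.filter_imu(v) for k, v in make_gait_acc(duration_s=60.0).items()}
    series = ft.compute_stride_time(acc, IntervalSet())
    assert len(series) > 40
    assert np.median(series.values) == pytest.approx(1.0, abs=0.05)


def test_stride_time_excludes_interruptions():
    pauses = [(20.0, 40.0)]
    acc = {k: pp.filter_imu(v) for k, v in make_gait_acc(duration_s=60.0, pauses=pauses).items()}
    iv = IntervalSet.from_raw(pauses)
    series = ft.compute_stride_time(acc, iv)
    assert len(series) > 0
    assert not np.any(iv.contains(series.timestamps))


def test_stride_time_slowdown_window():
    # 20 % longer stride period mid-trip
    fs = 50.0
    t = np.arange(0.0, 120.0, 1 / fs)
    slow = ((t >= 50) & (t < 80)).astype(float)
    f_inst = 2.0 / (1.0 + 0.2 * slow)
    phase = np.cumsum(f_inst) / fs
    z = 1.0 + 0.8 * np.sin(2 * np.pi * phase)
    acc = {"acc_z": pp.filter_imu(SignalChannel("acc_z", fs, 0.0, z))}
    series = ft.compute_stride_time(acc, IntervalSet())
    inside = (series.timestamps >= 55) & (series.timestamps < 78)
    outside = series.timestamps < 45
    assert np.median(series.values[inside]) == pytest.approx(1.2, abs=0.05)
    assert np.median(series.values[outside]) == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# Bottom-up segmentation
# ---------------------------------------------------------------------------


def test_bottomup_constant_series_single_segment():
    seg = ft.bottomup_segment(np.full(32, 3.3), max_merge_cost=0.1)
    assert seg.n_segments == 1
    assert np.array_equal(seg.boundaries, [0, 32])
    assert seg.attributes[0] == pytest.approx(3.3)


def test_bottomup_step_series_boundary_at_eight():
    x = np.concatenate([np.zeros(8), np.full(8, 5.0)])
    seg = ft.bottomup_segment(x, max_merge_cost=0.5)
    assert 8 in seg.boundaries.tolist()
    assert seg.n_segments == 2
    assert exhaustive_single_boundary(x) == 8


def test_bottomup_infinite_cap_merges_all(rng):
    x = rng.normal(0, 1, 37)
    seg = ft.bottomup_segment(x, max_merge_cost=np.inf)
    assert seg.n_segments == 1
    assert seg.attributes[0] == pytest.approx(x.mean())


def test_bottomup_matches_exhaustive_on_single_changepoint():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(8, 64))
        cut = int(rng.integers(2, n - 2)) & ~1  # even cut: initial 2-blocks align
        cut = max(cut, 2)
        a, bd = rng.normal(0, 0.0, 2)
        lo, hi = sorted(rng.normal(0, 5, 2))
        if hi - lo < 1:
            hi = lo + 2
        x = np.concatenate([np.full(cut, lo), np.full(n - cut, hi)])
        seg = ft.bottomup_segment(x, max_merge_cost=0.25 * (hi - lo) ** 2)
        assert cut in seg.boundaries.tolist()
        assert exhaustive_single_boundary(x) == cut


def test_bottomup_rejects_tiny_series():
    with pytest.raises(ValueError):
        ft.bottomup_segment(np.array([1.0]), 1.0)


# ---------------------------------------------------------------------------
# PSC
# ---------------------------------------------------------------------------


def test_psc_constant_series_zero():
    x = np.full(16, 2.0)
    seg = ft.bottomup_segment(x, max_merge_cost=np.inf)
    assert np.allclose(ft.compute_psc(x, seg), 0.0)


def test_psc_middle_segment_most_salient():
    x = np.concatenate([np.zeros(8), np.full(8, 10.0), np.zeros(8)])
    seg = ft.SegmentBoundaries(np.array([0, 8, 16, 24]), np.array([0.0, 10.0, 0.0]))
    psc = ft.compute_psc(x, seg)
    oracle = brute_force_psc(x, np.array([0, 8, 16, 24]))
    assert np.allclose(psc, oracle)
    assert psc[12] > psc[4] and psc[12] > psc[20]


def test_psc_mirror_symmetry():
    x = np.concatenate([np.zeros(6), np.full(4, 3.0), np.zeros(6)])
    seg = ft.SegmentBoundaries(np.array([0, 6, 10, 16]), np.array([0.0, 3.0, 0.0]))
    psc = ft.compute_psc(x, seg)
    assert np.allclose(psc, psc[::-1])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    data=st.data(),
    n=st.integers(min_value=4, max_value=64),
)
def test_psc_equals_brute_force(data, n):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    x = rng.normal(0, 1, n)
    n_cuts = int(rng.integers(0, min(6, n - 1)))
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_cuts, replace=False))
    b = np.concatenate([[0], cuts, [n]]).astype(int)
    attrs = np.array([x[b[i] : b[i + 1]].mean() for i in range(len(b) - 1)])
    seg = ft.SegmentBoundaries(b, attrs)
    for weighted in (True, False):
        ours = ft.compute_psc(x, seg, distance_weighted=weighted)
        oracle = brute_force_psc(x, b, weighted=weighted)
        assert np.allclose(ours, oracle, atol=1e-9)
        assert np.all(ours >= 0)


def test_psc_single_segment_zero(rng):
    x = rng.normal(0, 1, 20)
    seg = ft.SegmentBoundaries(np.array([0, 20]), np.array([x.mean()]))
    assert np.allclose(ft.compute_psc(x, seg), 0.0)


# ---------------------------------------------------------------------------
# Geocoding
# ---------------------------------------------------------------------------


def _track():
    return GeoTrack(np.array([0.0, 3.0, 6.0]), np.array([[0.0, 0.0], [6.0, 0.0], [6.0, 6.0]]))


def test_geocode_midpoint_between_fixes():
    fs = ft.FeatureSeries("scl", np.array([1.5]), np.array([2.0]))
    out = ft.geocode_features(fs, _track())
    assert np.allclose(out.positions[0], [3.0, 0.0])


def test_geocode_exactly_at_fix():
    fs = ft.FeatureSeries("scl", np.array([3.0]), np.array([2.0]))
    out = ft.geocode_features(fs, _track())
    assert np.allclose(out.positions[0], [6.0, 0.0])


def test_geocode_drops_out_of_span_samples():
    fs = ft.FeatureSeries("scl", np.array([-1.0, 2.0, 99.0]), np.array([1.0, 2.0, 3.0]))
    out = ft.geocode_features(fs, _track())
    assert len(out) == 1
    assert out.values[0] == 2.0


def test_geocode_stationary_track():
    track = GeoTrack(np.array([0.0, 3.0]), np.array([[5.0, 5.0], [5.0, 5.0]]))
    fs = ft.FeatureSeries("scl", np.array([0.5, 1.0, 2.5]), np.ones(3))
    out = ft.geocode_features(fs, track)
    assert np.allclose(out.positions, 5.0)
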