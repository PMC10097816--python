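"""Window-pair construction, mixed-effects fits and per-type t-tests."""

import numpy as np
import pandas as pd
import pytest

from walkstress import eventstats as es
from walkstress.features import FeatureSeries
from walkstress.io_formats import GeoTrack, StimulusReport
from walkstress.preprocess import IntervalSet


def _straight_track(duration=300.0, speed=1.4):
    t = np.arange(0.0, duration + 1e-9, 3.0)
    return GeoTrack(t, np.column_stack([speed * t, np.zeros_like(t)]))


def _flat_series(duration=300.0, value=1.0):
    t = np.arange(0.0, duration, 1.0)
    return FeatureSeries("scl", t, np.full_like(t, value))


def _report(track, t0, types=(1,)):
    pos = track.positions_at([t0])[0]
    return StimulusReport("t1", (float(pos[0]), float(pos[1])), types)


class TestExtractWindowPair:
    def test_midpoint_report_yields_pair(self):
        track = _straight_track()
        pair = es.extract_window_pair(track, 300.0, _report(track, 150.0), _flat_series(), 30.0)
        assert isinstance(pair, es.WindowPair)
        assert pair.nonstimuli_value == pytest.approx(1.0)
        assert pair.stimuli_value == pytest.approx(1.0)

    def test_early_report_truncated(self):
        track = _straight_track()
        out = es.extract_window_pair(track, 300.0, _report(track, 10.0), _flat_series(), 30.0)
        assert out == "truncated"

    def test_overlapping_stimuli_windows_exclude_later(self):
        track = _straight_track()
        r1, r2 = _report(track, 150.0), _report(track, 170.0)
        t01 = es.passage_time(track, r1.position)[0]
        t02 = es.passage_time(track, r2.position)[0]
        keep = es.extract_window_pair(
            track, 300.0, r1, _flat_series(), 60.0, other_t0s=np.array([t02])
        )
        drop = es.extract_window_pair(
            track, 300.0, r2, _flat_series(), 60.0, other_t0s=np.array([t01])
        )
        assert isinstance(keep, es.WindowPair)
        assert drop == "overlap"

    def test_off_route_report_excluded(self):
        track = _straight_track()
        rep = StimulusReport("t1", (210.0, 100.0), (1,))  # 100 m off the street
        assert es.extract_window_pair(track, 300.0, rep, _flat_series(), 30.0) == "off_route"

    def test_interrupted_window_excluded(self):
        track = _straight_track()
        iv = IntervalSet.from_raw([(120.0, 150.0)])  # kills the nonstimuli window
        out = es.extract_window_pair(
            track, 300.0, _report(track, 150.0), _flat_series(), 30.0, interruptions=iv
        )
        assert out == "interrupted"

    def test_exclusion_order_independent(self):
        track = _straight_track()
        reports = [_report(track, t) for t in (60.0, 150.0, 165.0, 250.0)]
        series = _flat_series()
        trip_data = {
            "t1": {
                "track": track,
                "duration_s": 300.0,
                "subject_id": "S0",
                "interruptions": IntervalSet(),
                "features": {"scl": series},
            }
        }
        kept_fwd = es.collect_pairs(trip_data, reports, "scl", 30.0)
        kept_rev = es.collect_pairs(trip_data, list(reversed(reports)), "scl", 30.0)
        assert sorted(p.t0_s for p in kept_fwd) == sorted(p.t0_s for p in kept_rev)


class TestFitLme:
    def test_zero_subject_variance_equals_pooled_ols(self, rng):
        import statsmodels.api as sm

        tab = es.simulate_pair_table(20, 10, beta=0.3, sigma_subject=0.0, sigma_resid=1.0, rng=rng)
        res = es.fit_lme(tab)
        X = sm.add_constant(tab["x"].to_numpy(float))
        ols = sm.OLS(tab["y"].to_numpy(float), X).fit()
        assert res.beta == pytest.approx(float(ols.params[1]), abs=1e-6)

    def test_recovers_injected_beta(self, rng):
        tab = es.simulate_pair_table(30, 20, beta=0.5, sigma_subject=1.0, sigma_resid=1.0, rng=rng)
        res = es.fit_lme(tab)
        assert res.beta == pytest.approx(0.5, abs=3 * res.beta_se)
        assert res.p_value < 0.05

    def test_constant_x_raises(self, rng):
        tab = es.simulate_pair_table(5, 5, 0.0, 1.0, 1.0, rng)
        tab["x"] = 1
        with pytest.raises(ValueError, match="no contrast"):
            es.fit_lme(tab)

    def test_too_few_subjects_raises(self, rng):
        tab = es.simulate_pair_table(1, 20, 0.0, 1.0, 1.0, rng)
        with pytest.raises(ValueError, match="subjects"):
            es.fit_lme(tab)


def _pairs_from_arrays(non, stim, types=(1,)):
    return [
        es.WindowPair("t", "s", types, 30.0, 100.0, float(a), float(b))
        for a, b in zip(non, stim)
    ]


class TestTTestByType:
    def test_identical_groups_t_zero_p_one(self):
        vals = np.linspace(0, 1, 10)
        res = es.ttest_by_type(_pairs_from_arrays(vals, vals), "scl", 30.0)
        assert len(res) == 1
        assert res[0].t_stat == 0.0
        assert res[0].p_value == 1.0
        assert not res[0].significant

    def test_separated_groups_significant(self, rng):
        non = rng.normal(0, 1, 50)
        stim = rng.normal(2, 1, 50)
        res = es.ttest_by_type(_pairs_from_arrays(non, stim), "scl", 30.0)
        # power ~1 at d=2, n=50: analytic noncentral-t power > 0.9999
        assert res[0].significant
        assert res[0].t_stat > 0

    def test_single_observation_undefined(self):
        res = es.ttest_by_type(_pairs_from_arrays([1.0], [2.0]), "scl", 30.0)
        assert res == []


class TestSweep:
    def test_empty_reports_empty_tables(self):
        track = _straight_track()
        trip_data = {
            "t1": {
                "track": track,
                "duration_s": 300.0,
                "subject_id": "S0",
                "interruptions": IntervalSet(),
                "features": {"scl": _flat_series()},
            }
        }
        lme, tt, minimal = es.sweep_window_lengths(trip_data, [], ["scl"], [30])
        assert lme.empty and tt.empty
        assert np.isnan(minimal["scl"])

    def test_injected_step_effect_detected_at_short_lengths(self, rng):
        # 12 subjects, one trip each; the feature steps up by 1.0 for 30 s
        # after passage at t=150, so short windows must reach significance
        trip_data = {}
        reports = []
        for i in range(12):
            track = _straight_track()
            t = np.arange(0.0, 300.0, 1.0)
            base = rng.normal(0, 0.2, len(t)) + rng.normal(0, 0.3)
            vals = base + np.where((t >= 150) & (t < 180), 1.0, 0.0)
            tid = f"t{i}"
            trip_data[tid] = {
                "track": track,
                "duration_s": 300.0,
                "subject_id": f"S{i}",
                "interruptions": IntervalSet(),
                "features": {"scl": FeatureSeries("scl", t, vals)},
            }
            rep = _report(track, 150.0)
            reports.append(StimulusReport(tid, rep.position, (2,)))
        lme, tt, minimal = es.sweep_window_lengths(
            trip_data, reports, ["scl"], [10, 30, 60], run_ttests=True
        )
        assert minimal["scl"] <= 30.0
        sig = tt[(tt["type"] == 2) & (tt["length_s"] == 30)]["significant"]
        assert bool(sig.iloc[0])
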