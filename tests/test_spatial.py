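"""POI segments, aggregation, labeling and Naive Bayes classification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from walkstress import spatial
from walkstress.features import FeatureSeries
from walkstress.io_formats import StimulusReport


def _street(length=100.0, y=0.0):
    return LineString([(0.0, y), (length, y)])


class TestBuildPoiSegments:
    def test_remainder_kept_when_at_least_half(self):
        segs = spatial.build_poi_segments([_street(100.0)], 40.0)
        spans = [(s.a_m, s.b_m) for s in segs]
        assert spans == [(0.0, 40.0), (40.0, 80.0), (80.0, 100.0)]

    def test_remainder_merged_when_short(self):
        segs = spatial.build_poi_segments([_street(100.0)], 30.0)
        spans = [(s.a_m, s.b_m) for s in segs]
        assert spans == [(0.0, 30.0), (30.0, 60.0), (60.0, 100.0)]

    def test_long_segment_whole_street(self):
        segs = spatial.build_poi_segments([_street(100.0)], 150.0)
        assert len(segs) == 1
        assert segs[0].length_m == pytest.approx(100.0)

    def test_spans_partition_street_exactly(self):
        for L in (1.0, 7.0, 40.0, 150.0):
            segs = spatial.build_poi_segments([_street(100.0)], L)
            assert sum(s.length_m for s in segs) == pytest.approx(100.0)
            bounds = [s.a_m for s in segs] + [segs[-1].b_m]
            assert bounds == sorted(bounds)

    def test_parallel_streets_buffers_disjoint(self):
        segs = spatial.build_poi_segments([_street(100.0, 0.0), _street(100.0, 100.0)], 40.0)
        a = [s for s in segs if s.street_id == 0]
        b = [s for s in segs if s.street_id == 1]
        assert not a[0].buffer.intersects(b[0].buffer)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            spatial.build_poi_segments([_street()], 0.0)


class TestAssignPoints:
    def test_point_in_overlapping_buffers_goes_to_nearer(self):
        # two parallel streets 60 m apart: buffers overlap in the middle
        segs = spatial.build_poi_segments([_street(100.0, 0.0), _street(100.0, 60.0)], 100.0)
        out = spatial.assign_points(segs, np.array([[50.0, 10.0], [50.0, 50.0]]))
        assert out[0] == segs[0].segment_id
        assert out[1] == segs[1].segment_id

    def test_equidistant_point_lower_segment_id(self):
        segs = spatial.build_poi_segments([_street(100.0, 0.0), _street(100.0, 60.0)], 100.0)
        out = spatial.assign_points(segs, np.array([[50.0, 30.0]]))
        assert out[0] == min(s.segment_id for s in segs)

    def test_point_outside_all_buffers_unassigned(self):
        segs = spatial.build_poi_segments([_street(100.0)], 100.0)
        out = spatial.assign_points(segs, np.array([[50.0, 90.0]]))
        assert out[0] == -1


def _feature_map_from_points(points, values, feature="scl", trip_id="t1"):
    return {
        trip_id: {
            feature: FeatureSeries(
                feature,
                np.arange(len(values), dtype=float),
                np.asarray(values, float),
                np.asarray(points, float),
            )
        }
    }


class TestAggregate:
    def test_constant_value_mean_and_zero_sd(self):
        segs = spatial.build_poi_segments([_street(100.0)], 100.0)
        fm = _feature_map_from_points([[10, 0], [50, 0], [90, 0]], [2.0, 2.0, 2.0])
        table = spatial.aggregate_to_segments(fm, segs, feature_names=("scl",), normalize=False)
        assert table.loc[segs[0].segment_id, "scl_mean"] == pytest.approx(2.0)
        assert table.loc[segs[0].segment_id, "scl_sd"] == pytest.approx(0.0)

    def test_empty_segment_absent(self):
        segs = spatial.build_poi_segments([_street(100.0)], 50.0)
        fm = _feature_map_from_points([[10, 0], [20, 0]], [1.0, 2.0])
        table = spatial.aggregate_to_segments(fm, segs, feature_names=("scl",), normalize=False)
        assert segs[0].segment_id in table.index
        assert segs[1].segment_id not in table.index

    def test_trip_order_invariance(self):
        segs = spatial.build_poi_segments([_street(100.0)], 50.0)
        fm1 = {
            **_feature_map_from_points([[10, 0]], [1.0], trip_id="a"),
            **_feature_map_from_points([[60, 0]], [5.0], trip_id="b"),
        }
        fm2 = dict(reversed(list(fm1.items())))
        t1 = spatial.aggregate_to_segments(fm1, segs, ("scl",), normalize=False)
        t2 = spatial.aggregate_to_segments(fm2, segs, ("scl",), normalize=False)
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())


class TestLabeling:
    def test_containment_rule(self):
        segs = spatial.build_poi_segments([_street(100.0)], 50.0)
        fm = _feature_map_from_points([[10, 0], [60, 0]], [1.0, 2.0])
        table = spatial.aggregate_to_segments(fm, segs, ("scl",), normalize=False)
        reports = [StimulusReport("t1", (15.0, 2.0), (1,))]
        table = spatial.label_segments(table, segs, reports)
        assert table.loc[segs[0].segment_id, "label"] == "stimuli"
        assert table.loc[segs[1].segment_id, "label"] == "nonstimuli"


def _gaussian_table(rng, n_per_class=60, sep=5.0):
    rows = []
    for label, mu in (("stimuli", sep), ("nonstimuli", 0.0)):
        for _ in range(n_per_class):
            rows.append(
                {
                    "scl_mean": rng.normal(mu, 1.0),
                    "scl_sd": rng.normal(mu, 1.0),
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


class TestClassify:
    def test_perfectly_separated_classes(self, rng):
        table = _gaussian_table(rng, sep=50.0)
        res = spatial.classify_segments(table, ("scl",), seed=0)
        assert res.uar == pytest.approx(1.0)

    def test_shuffled_labels_chance_level(self):
        uars = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = _gaussian_table(rng, n_per_class=60, sep=0.0)
            res = spatial.classify_segments(table, ("scl",), seed=seed)
            uars.append(res.uar)
        assert np.mean(uars) == pytest.approx(0.5, abs=0.05)

    def test_uar_from_confusion_counts(self):
        res = spatial.ClassificationResult(
            segment_length_m=40.0, feature_set=("scl",), tp=8, fn=2, tn=90, fp=10, n_folds=5
        )
        assert res.recall_stimuli == pytest.approx(0.8)
        assert res.recall_nonstimuli == pytest.approx(0.9)
        assert res.uar == pytest.approx(0.85)

    def test_minority_smaller_than_folds_warns_and_refolds(self, rng):
        table = _gaussian_table(rng, n_per_class=60, sep=3.0)
        table = pd.concat([table[table.label == "nonstimuli"], table[table.label == "stimuli"].head(3)])
        with pytest.warns(UserWarning, match="folds"):
            res = spatial.classify_segments(table, ("scl",), n_folds=5, seed=0)
        assert res.n_folds == 3

    def test_single_class_raises(self, rng):
        table = _gaussian_table(rng)
        table["label"] = "nonstimuli"
        with pytest.raises(ValueError):
            spatial.classify_segments(table, ("scl",), seed=0)


def test_sweep_reports_imbalance(tiny_study):
    from walkstress.pipeline import extract_study_features, trip_feature_map

    study = extract_study_features(tiny_study["trips"])
    res = spatial.sweep_segment_lengths(
        tiny_study["streets"],
        trip_feature_map(study),
        tiny_study["reports"],
        lengths=[5.0, 40.0],
        feature_sets={"all": spatial.CLASSIFIER_FEATURES},
        seed=0,
    )
    assert set(res["segment_length_m"]) == {5.0, 40.0}
    small = res[res.segment_length_m == 5.0].iloc[0]
    assert small["minority_share"] < 0.5
    assert (res["uar"] <= 1.0).all() and (res["uar"] >= 0.0).all()
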