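"""Location-based collective distress: street segments and classification.

Street centerlines are cut into consecutive POI segments of a chosen
length with a 40-m flat-capped buffer. Geocoded, per-trip z-normalized
feature points from all trips are assigned to the segment whose
centerline is nearest among the buffers containing the point, and
aggregated per segment as mean and standard deviation (12 values over
the six feature families). Segments holding at least one self-report are
labeled stimuli, all others nonstimuli. A Gaussian Naive Bayes
classifier under stratified fivefold cross-validation, scored with
unweighted average recall (UAR), measures how well the aggregated
biosignals separate the two classes; a sweep over segment lengths
(1, 5, 10, 20, ..., 150 m) probes spatial granularity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import LineString, Point, mapping
from shapely.ops import substring
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline

from .features import FeatureSeries
from .io_formats import StimulusReport

__all__ = [
    "PoiSegment",
    "ClassificationResult",
    "CLASSIFIER_FEATURES",
    "SEGMENT_LENGTHS_M",
    "build_poi_segments",
    "assign_points",
    "aggregate_to_segments",
    "label_segments",
    "classify_segments",
    "sweep_segment_lengths",
    "export_segment_geojson",
]

BUFFER_M = 40.0
SEGMENT_LENGTHS_M = [1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150]

#: The six feature families entering the classifier (mean + SD each).
CLASSIFIER_FEATURES = ("scl", "eda_psc", "stride_time", "imu_psc", "mean_hr", "bvp_psc")


@dataclass(frozen=True)
class PoiSegment:
    """One along-street span with its flat-capped buffer polygon."""

    segment_id: int
    street_id: int
    a_m: float
    b_m: float
    geometry: LineString
    buffer: object  # shapely Polygon

    @property
    def length_m(self) -> float:
        return self.b_m - self.a_m


@dataclass(frozen=True)
class ClassificationResult:
    """Pooled cross-validated confusion counts and per-class recalls."""

    segment_length_m: float
    feature_set: tuple[str, ...]
    tp: int
    fn: int
    tn: int
    fp: int
    n_folds: int

    @property
    def recall_stimuli(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def recall_nonstimuli(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def uar(self) -> float:
        return (self.recall_stimuli + self.recall_nonstimuli) / 2.0


def build_poi_segments(
    streets: list[LineString], length_m: float, buffer_m: float = BUFFER_M
) -> list[PoiSegment]:
    """Cut each centerline into consecutive spans of ``length_m``.

    A final remainder shorter than half the target length is merged into
    the previous span; otherwise it stands alone. Spans partition each
    street's length exactly.
    """
    if length_m <= 0:
        raise ValueError("length_m must be positive")
    segments: list[PoiSegment] = []
    sid = 0
    for street_id, ls in enumerate(streets):
        L = ls.length
        k = int(L // length_m)
        r = L - k * length_m
        cuts = [i * length_m for i in range(k + 1)]
        if r > 1e-9:
            if r >= length_m / 2 or k == 0:
                cuts.append(L)
            else:
                cuts[-1] = L
        for a, b in zip(cuts[:-1], cuts[1:]):
            geom = substring(ls, a, b)
            segments.append(
                PoiSegment(
                    segment_id=sid,
                    street_id=street_id,
                    a_m=a,
                    b_m=b,
                    geometry=geom,
                    buffer=geom.buffer(buffer_m, cap_style="flat"),
                )
            )
            sid += 1
    return segments


def assign_points(segments: list[PoiSegment], xy: np.ndarray) -> np.ndarray:
    """Segment id per point (or -1): nearest centerline among containing
    buffers, ties broken toward the lower segment id."""
    if len(xy) == 0:
        return np.array([], dtype=int)
    import shapely

    tree = STRtree([s.buffer for s in segments])
    pts = shapely.points(np.asarray(xy, float))
    pi, si = tree.query(pts, predicate="intersects")
    assign = np.full(len(pts), -1, dtype=int)
    if len(pi) == 0:
        return assign
    geoms = np.array([s.geometry for s in segments], dtype=object)
    ids = np.array([s.segment_id for s in segments])
    d = shapely.distance(pts[pi], geoms[si])
    # round distances so the lower-segment-id tie-break is deterministic
    d = np.round(d, 9)
    order = np.lexsort((si, d, pi))  # per point: nearest first, then lower id
    first = np.ones(len(order), dtype=bool)
    first[1:] = pi[order][1:] != pi[order][:-1]
    sel = order[first]
    assign[pi[sel]] = ids[si[sel]]
    return assign


def aggregate_to_segments(
    trip_features: dict[str, dict[str, FeatureSeries]],
    segments: list[PoiSegment],
    feature_names: tuple[str, ...] = CLASSIFIER_FEATURES,
    normalize: bool = True,
) -> pd.DataFrame:
    """Aggregate geocoded feature points into per-segment mean and SD.

    Features are z-normalized within each trip first (removing
    between-subject baseline differences), then pooled across all trips
    per segment. Segments without any point are absent from the output.
    """
    pts_by_feature: dict[str, list[np.ndarray]] = {f: [] for f in feature_names}
    vals_by_feature: dict[str, list[np.ndarray]] = {f: [] for f in feature_names}
    trips_by_feature: dict[str, list[np.ndarray]] = {f: [] for f in feature_names}
    for t_idx, (trip_id, feats) in enumerate(trip_features.items()):
        for f in feature_names:
            fs = feats.get(f)
            if fs is None or len(fs) == 0 or fs.positions is None:
                continue
            v = fs.values
            if normalize:
                sd = np.std(v)
                v = (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)
            pts_by_feature[f].append(fs.positions)
            vals_by_feature[f].append(v)
            trips_by_feature[f].append(np.full(len(v), t_idx))

    frames = []
    for f in feature_names:
        if not pts_by_feature[f]:
            continue
        xy = np.vstack(pts_by_feature[f])
        v = np.concatenate(vals_by_feature[f])
        tid = np.concatenate(trips_by_feature[f])
        seg = assign_points(segments, xy)
        ok = seg >= 0
        df = pd.DataFrame({"segment_id": seg[ok], "v": v[ok], "trip": tid[ok]})
        g = df.groupby("segment_id")["v"]
        out = pd.DataFrame(
            {
                f"{f}_mean": g.mean(),
                f"{f}_sd": g.std(ddof=0),
                f"{f}_n": g.size(),
            }
        )
        out[f"{f}_trips"] = df.groupby("segment_id")["trip"].nunique()
        frames.append(out)
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, axis=1)
    table.index.name = "segment_id"
    return table


def label_segments(
    table: pd.DataFrame, segments: list[PoiSegment], reports: list[StimulusReport]
) -> pd.DataFrame:
    """Attach the binary stimuli/nonstimuli label from report containment.

    A segment is ``stimuli`` iff at least one report falls to it under the
    same nearest-centerline rule used for feature points.
    """
    table = table.copy()
    table["label"] = "nonstimuli"
    if reports:
        xy = np.array([r.position for r in reports])
        seg = assign_points(segments, xy)
        stim_ids = set(int(s) for s in seg if s >= 0)
        table.loc[table.index.isin(stim_ids), "label"] = "stimuli"
    return table


def classify_segments(
    table: pd.DataFrame,
    feature_set: tuple[str, ...] = CLASSIFIER_FEATURES,
    n_folds: int = 5,
    seed: int = 0,
    segment_length_m: float = float("nan"),
) -> ClassificationResult:
    """Gaussian Naive Bayes with stratified k-fold CV, pooled over folds.

    Missing aggregates are imputed with the training-fold mean. If the
    minority class has fewer members than ``n_folds``, the fold count is
    reduced to keep both classes in every fold (with a warning).
    """
    cols = [f"{f}_{s}" for f in feature_set for s in ("mean", "sd")]
    cols = [c for c in cols if c in table.columns]
    if not cols:
        raise ValueError("no aggregate columns for the requested feature set")
    X = table[cols].to_numpy(float)
    # drop rows with no information at all
    keep = ~np.all(np.isnan(X), axis=1)
    X = X[keep]
    y = (table["label"].to_numpy() == "stimuli").astype(int)[keep]
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_min < 2:
        raise ValueError("need at least 2 samples in each class")
    k = min(n_folds, n_min)
    if k < n_folds:
        warnings.warn(f"minority class smaller than {n_folds}; using {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    for tr, te in skf.split(X, y):
        clf = make_pipeline(SimpleImputer(strategy="mean"), GaussianNB())
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        tp += int(np.sum((pred == 1) & (y[te] == 1)))
        fn += int(np.sum((pred == 0) & (y[te] == 1)))
        tn += int(np.sum((pred == 0) & (y[te] == 0)))
        fp += int(np.sum((pred == 1) & (y[te] == 0)))
    return ClassificationResult(
        segment_length_m=segment_length_m,
        feature_set=tuple(feature_set),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        n_folds=k,
    )


def predict_segment_probability(
    table: pd.DataFrame,
    feature_set: tuple[str, ...] = CLASSIFIER_FEATURES,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Cross-validated stimuli probability per segment (heat-map export)."""
    cols = [f"{f}_{s}" for f in feature_set for s in ("mean", "sd") if f"{f}_{s}" in table.columns]
    X = table[cols].to_numpy(float)
    y = (table["label"].to_numpy() == "stimuli").astype(int)
    proba = np.full(len(y), np.nan)
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_min < 2:
        return pd.Series(proba, index=table.index, name="p_stimuli")
    skf = StratifiedKFold(n_splits=min(n_folds, n_min), shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        clf = make_pipeline(SimpleImputer(strategy="mean"), GaussianNB())
        clf.fit(X[tr], y[tr])
        proba[te] = clf.predict_proba(X[te])[:, 1]
    return pd.Series(proba, index=table.index, name="p_stimuli")


def sweep_segment_lengths(
    streets: list[LineString],
    trip_features: dict[str, dict[str, FeatureSeries]],
    reports: list[StimulusReport],
    lengths: list[float] = SEGMENT_LENGTHS_M,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Classification results per (segment length, feature set).

    ``feature_sets`` defaults to each single family plus the all-feature
    set. The output also carries the class balance per length.
    """
    if feature_sets is None:
        feature_sets = {f: (f,) for f in CLASSIFIER_FEATURES}
        feature_sets["all"] = CLASSIFIER_FEATURES
    rows = []
    for L in lengths:
        segments = build_poi_segments(streets, float(L))
        table = aggregate_to_segments(trip_features, segments)
        if table.empty:
            continue
        table = label_segments(table, segments, reports)
        n_stim = int((table["label"] == "stimuli").sum())
        n_non = int((table["label"] == "nonstimuli").sum())
        for name, fs in feature_sets.items():
            try:
                res = classify_segments(table, fs, n_folds=n_folds, seed=seed, segment_length_m=L)
            except ValueError:
                continue
            rows.append(
                {
                    "segment_length_m": L,
                    "feature_set": name,
                    "uar": res.uar,
                    "recall_stimuli": res.recall_stimuli,
                    "recall_nonstimuli": res.recall_nonstimuli,
                    "n_stimuli": n_stim,
                    "n_nonstimuli": n_non,
                    "minority_share": n_stim / max(n_stim + n_non, 1),
                    "n_folds": res.n_folds,
                }
            )
    return pd.DataFrame(rows)


def export_segment_geojson(
    path: str,
    segments: list[PoiSegment],
    table: pd.DataFrame,
    proba: pd.Series | None = None,
) -> None:
    """Write labeled segment aggregates (and predicted probability) as GeoJSON."""
    feats = []
    for seg in segments:
        if seg.segment_id not in table.index:
            continue
        props = {"segment_id": seg.segment_id, "street_id": seg.street_id}
        row = table.loc[seg.segment_id]
        for k, v in row.items():
            props[str(k)] = v if isinstance(v, str) else (None if pd.isna(v) else float(v))
        if proba is not None and seg.segment_id in proba.index:
            p = proba.loc[seg.segment_id]
            props["p_stimuli"] = None if pd.isna(p) else float(p)
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(seg.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "crs": "local_m", "features": feats}, fh)
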