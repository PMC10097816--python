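"""Reading, writing and time alignment of wearable walking-trip recordings.

The on-disk conventions follow the export format of wrist-worn research
devices (one CSV per channel: first line the UTC start timestamp, second
line the sampling rate, then one sample per line; the accelerometer file
carries three comma-separated columns). Geotracks are CSV or GPX, street
centerlines are GeoJSON LineStrings, and stimulus self-reports are CSV
rows with a position and one or more of the fourteen canonical stimulus
types.

All internal computation is planar, in meters. Inputs declared as WGS84
are projected once at load time with a local equirectangular projection;
synthetic data is natively planar.
"""

from __future__ import annotations

import json
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

__all__ = [
    "FormatError",
    "STIMULUS_TYPES",
    "parse_stimulus_token",
    "SignalChannel",
    "GeoTrack",
    "WalkingTrip",
    "StimulusReport",
    "read_e4_channel",
    "write_e4_channel",
    "read_track",
    "write_track_csv",
    "read_reports_csv",
    "write_reports_csv",
    "read_streets_geojson",
    "write_streets_geojson",
    "read_geo_inputs",
    "align_trip",
    "project_wgs84",
    "MIN_OVERLAP_S",
]

CHANNEL_KINDS = ("eda", "bvp", "acc_x", "acc_y", "acc_z")

#: Canonical self-report stimulus vocabulary: nine undesirable presences and
#: five missing desirable elements.
STIMULUS_TYPES: dict[int, str] = {
    1: "poor walking surface",
    2: "blocked sidewalk",
    3: "steep sidewalk slope",
    4: "litter",
    5: "abandoned vehicle",
    6: "high speed of traffic",
    7: "unattended dogs",
    8: "rowdy people",
    9: "weather condition",
    10: "lack of sidewalk",
    11: "lack of crosswalk",
    12: "lack of benches",
    13: "lack of crosswalk and pedestrian light",
    14: "lack of street trees",
}

_NAME_TO_TYPE = {v: k for k, v in STIMULUS_TYPES.items()}

#: Channel time spans shorter than this after trimming make a trip unusable.
MIN_OVERLAP_S = 60.0


class FormatError(ValueError):
    """Raised when an input file does not match its expected dialect."""


def parse_stimulus_token(token: str | int) -> int:
    """Map a stimulus-type token (numeric id or name) to its canonical id.

    Unknown tokens raise :class:`FormatError` naming the offending token.
    """
    if isinstance(token, (int, np.integer)):
        tid = int(token)
        if tid not in STIMULUS_TYPES:
            raise FormatError(f"unknown stimulus type id: {tid!r}")
        return tid
    text = re.sub(r"\s+", " ", str(token)).strip().lower()
    if text.isdigit():
        return parse_stimulus_token(int(text))
    # strip a parenthetical qualifier, e.g. "litter (dumping, broken glass)"
    bare = re.sub(r"\s*\(.*\)\s*$", "", text)
    for candidate in (text, bare):
        if candidate in _NAME_TO_TYPE:
            return _NAME_TO_TYPE[candidate]
    raise FormatError(f"unknown stimulus type token: {token!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalChannel:
    """A single uniformly sampled sensor stream.

    Units: µS for ``eda``, arbitrary units for ``bvp``, g for ``acc_*``.
    ``start_time`` is in seconds (UTC epoch before alignment, seconds since
    trip start afterwards).
    """

    kind: str
    sampling_rate_hz: float
    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sampling_rate_hz

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def times(self) -> np.ndarray:
        """Sample timestamps, same clock as ``start_time``."""
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate_hz


@dataclass(frozen=True)
class GeoTrack:
    """A GPS trajectory: strictly increasing timestamps and planar positions.

    ``crs`` is ``"local_m"`` (planar meters) or ``"wgs84"`` (lon/lat degrees,
    converted at load time for any internal computation).
    """

    timestamps: np.ndarray
    positions: np.ndarray
    crs: str = "local_m"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(ts) != len(pos):
            raise ValueError("timestamps and positions length mismatch")
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(ts)) and np.all(np.isfinite(pos))):
            raise ValueError("track contains non-finite values")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def start_time(self) -> float:
        return float(self.timestamps[0])

    @property
    def end_time(self) -> float:
        return float(self.timestamps[-1])

    def positions_at(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated position at each time in ``t``."""
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.timestamps, self.positions[:, 0])
        y = np.interp(t, self.timestamps, self.positions[:, 1])
        return np.column_stack([x, y])


@dataclass
class WalkingTrip:
    """One subject's walking trip: raw channels, geotrack and metadata."""

    trip_id: str
    subject_id: str
    channels: dict[str, SignalChannel]
    track: GeoTrack
    quality_flags: set[str] = field(default_factory=set)

    def channel(self, kind: str) -> SignalChannel:
        return self.channels[kind]

    @property
    def duration_s(self) -> float:
        return self.track.end_time - self.track.start_time


@dataclass(frozen=True)
class StimulusReport:
    """A geocoded self-report of one or more negative environmental stimuli."""

    trip_id: str
    position: tuple[float, float]
    stimulus_types: tuple[int, ...]
    report_time: float | None = None
    stress_level: int | None = None

    def __post_init__(self) -> None:
        if not self.stimulus_types:
            raise ValueError("stimulus_types must be non-empty")
        for tid in self.stimulus_types:
            if tid not in STIMULUS_TYPES:
                raise FormatError(f"unknown stimulus type id: {tid!r}")


# ---------------------------------------------------------------------------
# Per-channel CSV (device-export dialect)
# ---------------------------------------------------------------------------


def _parse_float(text: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}: line {lineno}: non-numeric {what}: {text.strip()!r}"
        ) from None


def read_e4_channel(path: str | Path, kind: str) -> SignalChannel | list[SignalChannel]:
    """Read a per-channel CSV (header: start timestamp, sampling rate).

    ``kind='acc'`` reads the three-column accelerometer file and returns the
    three axis channels ``[acc_x, acc_y, acc_z]``.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: missing header (need timestamp + rate lines)")
    ncol = 3 if kind == "acc" else 1
    start_fields = lines[0].split(",")
    rate_fields = lines[1].split(",")
    start = _parse_float(start_fields[0], path, 1, "start timestamp")
    rate = _parse_float(rate_fields[0], path, 2, "sampling rate")
    if rate <= 0:
        raise FormatError(f"{path}: line 2: sampling rate must be positive")
    body = lines[2:]
    if not body:
        raise FormatError(f"{path}: empty channel body")
    rows = np.empty((len(body), ncol))
    for i, line in enumerate(body):
        parts = line.split(",")
        if len(parts) != ncol:
            raise FormatError(
                f"{path}: line {i + 3}: expected {ncol} column(s), got {len(parts)}"
            )
        for j, p in enumerate(parts):
            rows[i, j] = _parse_float(p, path, i + 3, "sample")
    if kind == "acc":
        return [
            SignalChannel(f"acc_{ax}", rate, start, rows[:, j])
            for j, ax in enumerate("xyz")
        ]
    if kind not in CHANNEL_KINDS:
        raise FormatError(f"unknown channel kind {kind!r}")
    return SignalChannel(kind, rate, start, rows[:, 0])


def write_e4_channel(path: str | Path, channels: SignalChannel | Sequence[SignalChannel]) -> None:
    """Write one channel (or the three ACC axes) in the per-channel dialect.

    Floats are written at full round-trip precision.
    """
    if isinstance(channels, SignalChannel):
        chans = [channels]
    else:
        chans = list(channels)
    start = chans[0].start_time
    rate = chans[0].sampling_rate_hz
    n = len(chans[0])
    for c in chans[1:]:
        if (c.start_time, c.sampling_rate_hz, len(c)) != (start, rate, n):
            raise ValueError("multi-column channels must share start/rate/length")
    cols = np.column_stack([c.values for c in chans])
    with open(path, "w") as fh:
        fh.write(f"{float(start)!r}\n{float(rate)!r}\n")
        for row in cols:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Geotracks, reports, streets
# ---------------------------------------------------------------------------


def project_wgs84(lonlat: np.ndarray, ref: tuple[float, float] | None = None) -> np.ndarray:
    """Project lon/lat degrees to local planar meters (equirectangular).

    Adequate at neighborhood scale (sub-meter error over a few km). ``ref``
    defaults to the first point.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    if ref is None:
        ref = (float(lonlat[0, 0]), float(lonlat[0, 1]))
    lon0, lat0 = ref
    r_earth = 6371008.8
    x = np.radians(lonlat[:, 0] - lon0) * r_earth * math.cos(math.radians(lat0))
    y = np.radians(lonlat[:, 1] - lat0) * r_earth
    return np.column_stack([x, y])


def read_track(path: str | Path, crs: str = "local_m") -> GeoTrack:
    """Read a geotrack from CSV (``time_s,x,y``) or GPX (``.gpx`` suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        return _read_gpx(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("time_s") or cols.get("t") or cols.get("timestamp")
    if tcol is None:
        raise FormatError(f"{path}: no time column (expected time_s)")
    if "x" in cols and "y" in cols:
        pos = df[[cols["x"], cols["y"]]].to_numpy(float)
        return GeoTrack(df[tcol].to_numpy(float), pos, crs="local_m")
    if "lon" in cols and "lat" in cols:
        lonlat = df[[cols["lon"], cols["lat"]]].to_numpy(float)
        return GeoTrack(df[tcol].to_numpy(float), lonlat, crs="wgs84")
    raise FormatError(f"{path}: need x/y or lon/lat columns")


def _read_gpx(path: Path) -> GeoTrack:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed GPX: {exc}") from None
    pts = root.findall(".//gpx:trkpt", ns) or root.findall(".//trkpt")
    if not pts:
        raise FormatError(f"{path}: no trkpt elements")
    lonlat, times = [], []
    for p in pts:
        lonlat.append((float(p.get("lon")), float(p.get("lat"))))
        t = p.find("gpx:time", ns)
        if t is None:
            t = p.find("time")
        if t is None:
            raise FormatError(f"{path}: trkpt without time element")
        times.append(pd.Timestamp(t.text).timestamp())
    return GeoTrack(np.asarray(times), np.asarray(lonlat), crs="wgs84")


def write_track_csv(path: str | Path, track: GeoTrack) -> None:
    xcol, ycol = ("x", "y") if track.crs == "local_m" else ("lon", "lat")
    with open(path, "w") as fh:
        fh.write(f"time_s,{xcol},{ycol}\n")
        for t, (x, y) in zip(track.timestamps, track.positions):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")


def read_reports_csv(path: str | Path, crs: str = "local_m") -> list[StimulusReport]:
    """Read stimulus reports: ``trip_id,x,y,types[,time_s,stress]``.

    ``types`` is a semicolon-separated list of ids or names; unknown tokens
    raise :class:`FormatError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    xcol = cols.get("x") or cols.get("lon")
    ycol = cols.get("y") or cols.get("lat")
    if xcol is None or ycol is None:
        raise FormatError(f"{path}: need x/y or lon/lat columns")
    reports = []
    for _, row in df.iterrows():
        types = tuple(
            parse_stimulus_token(tok)
            for tok in str(row[cols["types"]]).split(";")
            if tok.strip()
        )
        rtime = None
        if "time_s" in cols and not pd.isna(row[cols["time_s"]]):
            rtime = float(row[cols["time_s"]])
        stress = None
        if "stress" in cols and not pd.isna(row[cols["stress"]]):
            stress = int(row[cols["stress"]])
        reports.append(
            StimulusReport(
                trip_id=str(row[cols["trip_id"]]),
                position=(float(row[xcol]), float(row[ycol])),
                stimulus_types=types,
                report_time=rtime,
                stress_level=stress,
            )
        )
    return reports


def write_reports_csv(path: str | Path, reports: Iterable[StimulusReport]) -> None:
    with open(path, "w") as fh:
        fh.write("trip_id,x,y,types,time_s,stress\n")
        for r in reports:
            types = ";".join(str(t) for t in r.stimulus_types)
            rtime = "" if r.report_time is None else repr(float(r.report_time))
            stress = "" if r.stress_level is None else str(r.stress_level)
            fh.write(
                f"{r.trip_id},{float(r.position[0])!r},{float(r.position[1])!r},{types},{rtime},{stress}\n"
            )


def read_streets_geojson(path: str | Path) -> tuple[list[LineString], str]:
    """Read street centerlines; returns (linestrings, crs tag)."""
    with open(path) as fh:
        gj = json.load(fh)
    crs = gj.get("crs", "wgs84")
    if isinstance(crs, dict):  # legacy named-CRS object
        crs = "wgs84"
    feats = gj.get("features", [])
    lines: list[LineString] = []
    for feat in feats:
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(geom.geoms)
        else:
            raise FormatError(f"{path}: unsupported geometry {geom.geom_type}")
    if not lines:
        raise FormatError(f"{path}: no LineString features")
    return lines, crs


def write_streets_geojson(path: str | Path, streets: Sequence[LineString], crs: str = "local_m") -> None:
    gj = {
        "type": "FeatureCollection",
        "crs": crs,
        "features": [
            {"type": "Feature", "properties": {"street_id": i}, "geometry": mapping(ls)}
            for i, ls in enumerate(streets)
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_geo_inputs(
    track_path: str | Path,
    reports_path: str | Path,
    streets_path: str | Path,
) -> tuple[GeoTrack, list[StimulusReport], list[LineString]]:
    """Load a geotrack, report table and street collection on one planar CRS.

    WGS84 inputs are projected to local meters using the first track point as
    the reference; mixing a planar track with WGS84 streets (or vice versa) is
    an error because no common reference exists.
    """
    track = read_track(track_path)
    streets, street_crs = read_streets_geojson(streets_path)
    reports = read_reports_csv(reports_path)
    if track.crs == "wgs84" and street_crs == "wgs84":
        ref = (float(track.positions[0, 0]), float(track.positions[0, 1]))
        track = GeoTrack(
            track.timestamps, project_wgs84(track.positions, ref), crs="local_m"
        )
        streets = [
            LineString(project_wgs84(np.asarray(ls.coords), ref)) for ls in streets
        ]
        reports = [
            replace(
                r,
                position=tuple(
                    project_wgs84(np.asarray([r.position]), ref)[0]
                ),
            )
            for r in reports
        ]
    elif track.crs != street_crs:
        raise FormatError(
            f"CRS mismatch: track is {track.crs!r}, streets are {street_crs!r}; "
            "project inputs to a common CRS first"
        )
    return track, reports, streets


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_trip(trip: WalkingTrip) -> WalkingTrip:
    """Re-express all channels and the track on seconds since trip start.

    Channels are trimmed to the overlap of all channel and track spans; no
    resampling is performed (each feature extractor works at native rate).
    Trips whose common span is shorter than :data:`MIN_OVERLAP_S` are flagged
    ``unusable``. Idempotent.
    """
    spans = [(c.start_time, c.end_time) for c in trip.channels.values()]
    spans.append((trip.track.start_time, trip.track.end_time))
    t0 = max(s for s, _ in spans)
    t1 = min(e for _, e in spans)
    flags = set(trip.quality_flags)
    if t1 - t0 < MIN_OVERLAP_S:
        flags.add("unusable")
        return WalkingTrip(trip.trip_id, trip.subject_id, dict(trip.channels), trip.track, flags)

    new_channels: dict[str, SignalChannel] = {}
    for kind, ch in trip.channels.items():
        i0 = int(np.ceil((t0 - ch.start_time) * ch.sampling_rate_hz - 1e-9))
        i1 = int(np.floor((t1 - ch.start_time) * ch.sampling_rate_hz + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(ch))
        start_rel = ch.start_time + i0 / ch.sampling_rate_hz - t0
        new_channels[kind] = SignalChannel(
            kind, ch.sampling_rate_hz, start_rel, ch.values[i0:i1]
        )
    # keep interior fixes and interpolate boundary fixes at exactly t0 and t1
    mask = (trip.track.timestamps > t0 + 1e-9) & (trip.track.timestamps < t1 - 1e-9)
    ts = np.concatenate([[t0], trip.track.timestamps[mask], [t1]])
    pos = np.vstack(
        [
            trip.track.positions_at([t0]),
            trip.track.positions[mask],
            trip.track.positions_at([t1]),
        ]
    )
    track = GeoTrack(ts - t0, pos, crs=trip.track.crs)
    return WalkingTrip(trip.trip_id, trip.subject_id, new_channels, track, flags)
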