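"""Reading, writing and summarising encounter-annotated GPS tracks.

A track is a sequence of timestamped fixes recorded at a nominal 10 s
cadence while a forager searches. Encounters with prey are sparse point
events annotated either as GPX waypoints or as a CSV of timestamps; each
annotation is matched to the nearest fix in time and stored as a binary
flag (with a hit / non-hit subtype when known).
"""

from __future__ import annotations

import io
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .projection import LocalProjection

GPX_NS = "http://www.topografix.com/GPX/1/1"

#: Nominal seconds between fixes.
CADENCE_S = 10.0
#: Tolerated jitter around the nominal cadence before a step is flagged.
CADENCE_TOL_S = 2.0
#: Inter-fix gaps longer than this (more than one missed fix) split the
#: series into separate segments for lag purposes.
GAP_SPLIT_S = 2 * CADENCE_S + CADENCE_TOL_S

ENCOUNTER_KINDS = ("none", "hit", "nonhit")


class TrackError(ValueError):
    """Raised for malformed or unusable track input."""


@dataclass(frozen=True)
class CadenceReport:
    """Summary of how well a track adheres to the nominal fix cadence."""

    nominal_s: float
    median_dt_s: float
    n_deviations: int          # steps where |dt - nominal| > tolerance
    split_indices: tuple[int, ...]  # step indices whose gap splits the series

    @property
    def ok(self) -> bool:
        return self.n_deviations == 0


@dataclass
class Track:
    """Timestamped planar fixes with encounter flags for one trip.

    ``t`` holds seconds since trip start; ``xy`` holds meters in a local
    tangent plane centred on the track. ``E`` is a 0/1 encounter flag per
    fix and ``E_kind`` its subtype (``none`` exactly where ``E`` is 0).
    """

    trip_id: str
    t: np.ndarray
    xy: np.ndarray
    lonlat: np.ndarray | None = None
    elev: np.ndarray | None = None
    E: np.ndarray = None
    E_kind: np.ndarray = None
    projection: LocalProjection | None = None
    start_time: datetime | None = None
    cadence: CadenceReport | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        n = self.t.size
        if self.xy.shape != (n, 2):
            raise TrackError(f"xy must be ({n}, 2), got {self.xy.shape}")
        if n < 2:
            raise TrackError("degenerate track: fewer than 2 fixes")
        if not np.all(np.diff(self.t) > 0):
            raise TrackError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise TrackError("xy contains non-finite coordinates")
        if self.E is None:
            self.E = np.zeros(n, dtype=np.int8)
        self.E = np.asarray(self.E, dtype=np.int8)
        if self.E_kind is None:
            self.E_kind = np.where(self.E == 1, "nonhit", "none")
        self.E_kind = np.asarray(self.E_kind, dtype=object)
        if self.E.shape != (n,) or self.E_kind.shape != (n,):
            raise TrackError("E / E_kind must match the number of fixes")
        if not np.array_equal(self.E_kind == "none", self.E == 0):
            raise TrackError("E_kind must be 'none' exactly where E == 0")
        if self.cadence is None:
            self.cadence = _cadence_report(self.t)

    @property
    def n_fixes(self) -> int:
        return self.t.size

    def segments(self) -> list[slice]:
        """Contiguous index ranges separated by cadence gaps.

        Lagged quantities must not carry over a gap of more than one
        missed fix, so downstream code treats each segment independently.
        """
        cuts = [0, *[i + 1 for i in self.cadence.split_indices], self.n_fixes]
        return [slice(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b - a >= 2]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"trip_id": self.trip_id, "t": self.t,
             "x": self.xy[:, 0], "y": self.xy[:, 1],
             "E": self.E, "E_kind": self.E_kind}
        )
        if self.elev is not None:
            df["elev"] = self.elev
        return df


@dataclass(frozen=True)
class HuntSummary:
    """Per-trip descriptive statistics (distance, duration, speed, counts)."""

    trip_id: str
    n_fixes: int
    dist_km: float
    duration_hr: float
    avg_speed_kmh: float
    elev_change_m: float | None
    n_encounters: int
    n_shots: int | None = None
    n_hits: int | None = None
    n_recovered: int | None = None


def _cadence_report(t: np.ndarray, nominal: float = CADENCE_S,
                    tol: float = CADENCE_TOL_S) -> CadenceReport:
    dt = np.diff(t)
    deviations = int(np.sum(np.abs(dt - nominal) > tol))
    splits = tuple(int(i) for i in np.flatnonzero(dt > GAP_SPLIT_S))
    return CadenceReport(nominal, float(np.median(dt)), deviations, splits)


def _parse_time(text: str) -> datetime:
    dt = datetime.fromisoformat(text.strip().replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _gpx_root(source) -> ET.Element:
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        return ET.parse(source).getroot()
    if isinstance(source, str):
        return ET.fromstring(source)
    if isinstance(source, bytes):
        return ET.fromstring(source.decode())
    return ET.parse(source).getroot()


def read_track(gpx_source, trip_id: str | None = None) -> Track:
    """Read one GPX track into a :class:`Track` in a local planar frame.

    All ``<trkpt>`` elements (across segments) of the first ``<trk>`` are
    used, sorted into temporal order; lon/lat are projected onto a tangent
    plane centred on the track centroid and a cadence report is attached.
    """
    root = _gpx_root(gpx_source)
    trks = [el for el in root.iter() if _localname(el.tag) == "trk"]
    scope = trks[0] if trks else root
    name_el = next((el for el in scope.iter() if _localname(el.tag) == "name"), None)
    if trip_id is None:
        trip_id = (name_el.text.strip() if name_el is not None and name_el.text
                   else "track")

    times, lons, lats, elevs = [], [], [], []
    for pt in scope.iter():
        if _localname(pt.tag) != "trkpt":
            continue
        lons.append(float(pt.attrib["lon"]))
        lats.append(float(pt.attrib["lat"]))
        t_el = next((c for c in pt if _localname(c.tag) == "time"), None)
        if t_el is None or not t_el.text:
            raise TrackError(f"untimed track: trackpoint without <time> in {trip_id!r}")
        times.append(_parse_time(t_el.text))
        e_el = next((c for c in pt if _localname(c.tag) == "ele"), None)
        elevs.append(float(e_el.text) if e_el is not None and e_el.text else np.nan)

    if len(times) < 2:
        raise TrackError(f"degenerate track: {len(times)} trackpoint(s) in {trip_id!r}")

    order = np.argsort(np.array([t.timestamp() for t in times]))
    lon = np.array(lons)[order]
    lat = np.array(lats)[order]
    elev = np.array(elevs)[order]
    stamps = np.array([times[i].timestamp() for i in order])

    proj = LocalProjection(float(lon.mean()), float(lat.mean()))
    x, y = proj.forward(lon, lat)
    return Track(
        trip_id=trip_id,
        t=stamps - stamps[0],
        xy=np.column_stack([x, y]),
        lonlat=np.column_stack([lon, lat]),
        elev=None if np.all(np.isnan(elev)) else elev,
        projection=proj,
        start_time=times[order[0]],
    )


def read_tracks(directory) -> list[Track]:
    """Read every ``*.gpx`` file in a directory (sorted by name)."""
    paths = sorted(p for p in os.listdir(directory) if p.lower().endswith(".gpx"))
    if not paths:
        raise TrackError(f"no GPX files found in {directory!r}")
    return [read_track(os.path.join(directory, p),
                       trip_id=os.path.splitext(p)[0]) for p in paths]


def write_gpx(track: Track, path, creator: str = "ars-search") -> None:
    """Write a track (and its encounter waypoints) as GPX 1.1."""
    start = track.start_time or datetime(2000, 1, 1, tzinfo=timezone.utc)
    if track.lonlat is not None:
        lon, lat = track.lonlat[:, 0], track.lonlat[:, 1]
    else:
        proj = track.projection or LocalProjection(0.0, 0.0)
        lon, lat = proj.inverse(track.xy[:, 0], track.xy[:, 1])

    ET.register_namespace("", GPX_NS)
    root = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator=creator)
    for i in np.flatnonzero(track.E):
        wpt = ET.SubElement(root, f"{{{GPX_NS}}}wpt",
                            lat=f"{lat[i]:.8f}", lon=f"{lon[i]:.8f}")
        ET.SubElement(wpt, f"{{{GPX_NS}}}time").text = (
            (start + timedelta(seconds=float(track.t[i]))).isoformat())
        ET.SubElement(wpt, f"{{{GPX_NS}}}name").text = str(track.E_kind[i])
    trk = ET.SubElement(root, f"{{{GPX_NS}}}trk")
    ET.SubElement(trk, f"{{{GPX_NS}}}name").text = track.trip_id
    seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
    for i in range(track.n_fixes):
        pt = ET.SubElement(seg, f"{{{GPX_NS}}}trkpt",
                           lat=f"{lat[i]:.8f}", lon=f"{lon[i]:.8f}")
        if track.elev is not None and np.isfinite(track.elev[i]):
            ET.SubElement(pt, f"{{{GPX_NS}}}ele").text = f"{track.elev[i]:.2f}"
        ET.SubElement(pt, f"{{{GPX_NS}}}time").text = (
            (start + timedelta(seconds=float(track.t[i]))).isoformat())
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def read_annotations(source) -> pd.DataFrame:
    """Read encounter annotations from a GPX waypoint file or a CSV.

    Returns a frame with columns ``trip_id`` (may be NA), ``timestamp``
    (tz-aware) and ``kind`` in {hit, nonhit}.
    """
    is_path = isinstance(source, (str, os.PathLike)) and os.path.exists(source)
    text = None
    if is_path:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    if text is not None and text.lstrip().startswith("<"):
        root = ET.fromstring(text)
        rows = []
        for wpt in root.iter():
            if _localname(wpt.tag) != "wpt":
                continue
            t_el = next((c for c in wpt if _localname(c.tag) == "time"), None)
            if t_el is None or not t_el.text:
                raise TrackError("annotation waypoint without <time>")
            n_el = next((c for c in wpt if _localname(c.tag) == "name"), None)
            kind = (n_el.text or "").strip().lower() if n_el is not None else ""
            rows.append({"trip_id": pd.NA, "timestamp": _parse_time(t_el.text),
                         "kind": kind if kind in ("hit", "nonhit") else "nonhit"})
        return pd.DataFrame(rows, columns=["trip_id", "timestamp", "kind"])

    df = pd.read_csv(io.StringIO(text) if text is not None else source)
    required = {"timestamp_iso8601", "kind"}
    if not required.issubset(df.columns):
        raise TrackError(f"annotation CSV needs columns {sorted(required)}")
    bad = ~df["kind"].isin(["hit", "nonhit"])
    if bad.any():
        raise TrackError(f"unknown encounter kinds: {sorted(df.loc[bad, 'kind'].unique())}")
    out = pd.DataFrame({
        "trip_id": df["trip_id"] if "trip_id" in df else pd.NA,
        "timestamp": df["timestamp_iso8601"].map(_parse_time),
        "kind": df["kind"],
    })
    return out


def align_encounters(track: Track, annotations: pd.DataFrame,
                     tolerance_s: float = CADENCE_S) -> Track:
    """Flag, for each annotation, the nearest fix in time (ties -> earlier).

    Annotations carrying a ``trip_id`` are filtered to this track first.
    Any annotation falling outside the track's time range by more than
    ``tolerance_s`` raises an error listing the offenders.
    """
    ann = annotations
    if "trip_id" in ann.columns and ann["trip_id"].notna().any():
        ann = ann[ann["trip_id"].astype("string") == str(track.trip_id)]
    if ann.empty:
        return track
    if track.start_time is None:
        raise TrackError("track has no absolute start time to align against")

    t0 = track.start_time.timestamp()
    rel = np.array([ts.timestamp() - t0 for ts in ann["timestamp"]])
    out_of_range = (rel < track.t[0] - tolerance_s) | (rel > track.t[-1] + tolerance_s)
    if out_of_range.any():
        offenders = ann.loc[np.asarray(out_of_range), "timestamp"].tolist()
        raise TrackError(
            f"annotations outside track {track.trip_id!r} time range "
            f"(tolerance {tolerance_s}s): {offenders}")

    E = track.E.copy()
    kind = track.E_kind.copy()
    for r, k in zip(rel, ann["kind"]):
        diffs = np.abs(track.t - r)
        best = float(diffs.min())
        idx = int(np.flatnonzero(diffs == best)[0])  # tie -> earlier fix
        E[idx] = 1
        kind[idx] = k
    return replace(track, E=E, E_kind=kind, cadence=track.cadence)


def hunt_summary(track: Track) -> HuntSummary:
    """Distance, duration, speed, elevation range and encounter counts."""
    steps = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dist_km = float(steps.sum()) / 1000.0
    duration_hr = float(track.t[-1] - track.t[0]) / 3600.0
    elev_change = None
    if track.elev is not None:
        finite = track.elev[np.isfinite(track.elev)]
        if finite.size:
            elev_change = float(finite.max() - finite.min())
    n_hits = int(np.sum(track.E_kind == "hit"))
    return HuntSummary(
        trip_id=track.trip_id,
        n_fixes=track.n_fixes,
        dist_km=dist_km,
        duration_hr=duration_hr,
        avg_speed_kmh=dist_km / duration_hr if duration_hr > 0 else float("nan"),
        elev_change_m=elev_change,
        n_encounters=int(track.E.sum()),
        n_shots=track.meta.get("n_shots"),
        n_hits=track.meta.get("n_hits", n_hits if n_hits else None),
        n_recovered=track.meta.get("n_recovered"),
    )


def summary_table(tracks: Sequence[Track]) -> pd.DataFrame:
    """Per-trip descriptives with a Sum and Mean row, one trip per row."""
    rows = [hunt_summary(tr).__dict__ for tr in tracks]
    df = pd.DataFrame(rows).set_index("trip_id")
    num = df.select_dtypes("number")
    df.loc["Sum"] = num.sum()
    df.loc["Mean"] = num.mean()
    return df
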