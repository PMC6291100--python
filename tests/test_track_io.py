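"""GPX reading/writing, encounter alignment and per-hunt descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ars_search import (SimConfig, Track, align_encounters, hunt_summary,
                        read_annotations, read_track, simulate_forager,
                        summary_table, write_gpx)
from ars_search.projection import LocalProjection
from ars_search.track_io import TrackError


def test_read_track_3pt(gpx_3pt):
    tr = read_track(gpx_3pt)
    assert tr.n_fixes == 3
    assert tr.trip_id == "mini"
    assert tr.cadence.ok
    assert tr.elev is not None and tr.elev[2] == pytest.approx(1502.5)
    # ~5.5 m between the first two fixes (0.00005 deg latitude)
    assert np.linalg.norm(tr.xy[1] - tr.xy[0]) == pytest.approx(5.56, abs=0.1)


def test_read_track_errors(gpx_untimed):
    with pytest.raises(TrackError, match="untimed track"):
        read_track(gpx_untimed)
    single = (
        '<gpx xmlns="http://www.topografix.com/GPX/1/1"><trk><trkseg>'
        '<trkpt lat="5" lon="-75"><time>2017-03-01T06:00:00Z</time></trkpt>'
        "</trkseg></trk></gpx>")
    with pytest.raises(TrackError, match="degenerate track"):
        read_track(single)


def test_projection_roundtrip_cm():
    proj = LocalProjection(-75.9, 5.1)
    rng = np.random.default_rng(0)
    x = rng.uniform(-5000, 5000, 200)
    y = rng.uniform(-5000, 5000, 200)
    lon, lat = proj.inverse(x, y)
    x2, y2 = proj.forward(lon, lat)
    assert np.max(np.hypot(x2 - x, y2 - y)) < 0.01


def _planar_track(xy, t=None, **kw):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * 10.0 if t is None else np.asarray(t, float)
    return Track(trip_id="t", t=t, xy=xy, **kw)


def test_hunt_summary_basics():
    tr = _planar_track([(0.0, 0.0), (5.0, 0.0)])
    s = hunt_summary(tr)
    assert s.dist_km == pytest.approx(0.005)
    assert s.duration_hr == pytest.approx(10 / 3600)
    assert s.avg_speed_kmh == pytest.approx(1.8)
    assert s.elev_change_m is None           # absent, not zero
    assert s.n_encounters == 0

    line = np.column_stack([np.arange(11.0) * 2, np.zeros(11)])
    assert hunt_summary(_planar_track(line)).dist_km == pytest.approx(0.020)


def test_hunt_summary_rigid_motion_invariance():
    rng = np.random.default_rng(3)
    xy = rng.normal(0, 30, (50, 2))
    d0 = hunt_summary(_planar_track(xy)).dist_km
    ang = 1.1
    R = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
    d1 = hunt_summary(_planar_track(xy @ R + np.array([123.0, -77.0]))).dist_km
    assert d1 == pytest.approx(d0, rel=1e-9)


def test_align_encounters_nearest_fix(gpx_3pt):
    tr = read_track(gpx_3pt)
    ann = pd.DataFrame({
        "trip_id": [pd.NA, pd.NA],
        "timestamp": pd.to_datetime(["2017-03-01T06:00:10Z",   # exact fix
                                     "2017-03-01T06:00:24Z"]), # 4 s after fix 2
        "kind": ["hit", "nonhit"],
    })
    out = align_encounters(tr, ann)
    assert list(np.flatnonzero(out.E)) == [1, 2]
    assert out.E_kind[1] == "hit" and out.E_kind[2] == "nonhit"

    late = ann.assign(timestamp=pd.to_datetime(["2017-03-01T07:00:00Z"] * 2))
    with pytest.raises(TrackError, match="outside track"):
        align_encounters(tr, late)


def test_align_tie_goes_to_earlier_fix(gpx_3pt):
    tr = read_track(gpx_3pt)
    ann = pd.DataFrame({"trip_id": [pd.NA],
                        "timestamp": pd.to_datetime(["2017-03-01T06:00:05Z"]),
                        "kind": ["nonhit"]})
    out = align_encounters(tr, ann)
    assert list(np.flatnonzero(out.E)) == [0]


@settings(deadline=None, max_examples=20)
@given(offsets=st.lists(st.floats(-5, 25), min_size=1, max_size=8))
def test_align_never_flags_more_than_annotations(offsets):
    from conftest import GPX_3PT

    tr = read_track(GPX_3PT)
    base = pd.Timestamp("2017-03-01T06:00:00Z")
    ann = pd.DataFrame({
        "trip_id": [pd.NA] * len(offsets),
        "timestamp": [base + pd.Timedelta(seconds=o) for o in offsets],
        "kind": ["nonhit"] * len(offsets),
    })
    out = align_encounters(tr, ann, tolerance_s=10)
    assert out.E.sum() <= len(offsets)


def test_annotation_csv_parsing(tmp_path):
    p = tmp_path / "ann.csv"
    p.write_text("trip_id,timestamp_iso8601,kind\n"
                 "mini,2017-03-01T06:00:10Z,hit\n"
                 "other,2017-03-01T06:00:20Z,nonhit\n")
    ann = read_annotations(str(p))
    assert len(ann) == 2 and set(ann["kind"]) == {"hit", "nonhit"}
    with pytest.raises(TrackError, match="unknown encounter kinds"):
        read_annotations("trip_id,timestamp_iso8601,kind\nx,2017-03-01T06:00:10Z,miss\n")


def test_gpx_roundtrip_preserves_geometry(tmp_path):
    sim = simulate_forager(SimConfig(n_trips=1, n_steps=200, seed=5), "ars", seed=5)
    tr = sim.tracks[0]
    path = tmp_path / "trip.gpx"
    write_gpx(tr, str(path))
    back = read_track(str(path))
    assert back.n_fixes == tr.n_fixes
    r0 = np.hypot(*np.diff(tr.xy, axis=0).T)
    r1 = np.hypot(*np.diff(back.xy, axis=0).T)
    assert np.max(np.abs(r0 - r1)) < 0.01      # cm-level coordinate precision
    # waypoints round-trip as annotations onto the same fixes
    ann = read_annotations(path.read_text())
    flagged = align_encounters(back, ann)
    assert np.array_equal(np.flatnonzero(flagged.E), np.flatnonzero(tr.E))


def test_summary_table_has_sum_and_mean_rows(gpx_3pt):
    tr = read_track(gpx_3pt)
    tab = summary_table([tr])
    assert {"Sum", "Mean"} <= set(tab.index)
    assert tab.loc["Sum", "n_fixes"] == 3


def test_cadence_gap_splits_segments():
    t = np.array([0, 10, 20, 80, 90, 100.0])     # 60 s hole: >1 missed fix
    xy = np.column_stack([np.arange(6.0) * 2, np.zeros(6)])
    tr = _planar_track(xy, t=t)
    assert tr.cadence.split_indices == (2,)
    assert [s.indices(6) for s in tr.segments()] == [(0, 3, 1), (3, 6, 1)]
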