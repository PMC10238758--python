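"""Fix-table I/O, epoch alignment, geometry primitives, cohort filters."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import BASE_LAT, BASE_LON, fixes_from_rows, fixture_config, offset_lonlat, square_polygon
from vulturenet.errors import ConfigurationError, EmptyInputError
from vulturenet.trajectory import (
    StudyConfig,
    bin_to_epochs,
    filter_individuals,
    great_circle_distance,
    load_roost_polygons,
    point_in_polygon,
    polygon_area_m2,
    read_fix_table,
    write_roost_polygons,
)


# ---------------------------------------------------------------------------
# reading fix tables
# ---------------------------------------------------------------------------

CSV_HEADER = "individual_id,timestamp,lon,lat,ground_speed\n"


def _write(tmp_path, text, name="fixes.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_well_formed_rows(tmp_path):
    p = _write(
        tmp_path,
        CSV_HEADER
        + "a,2021-01-01 08:00:00,35.0,30.5,1.0\n"
        + "a,2021-01-01 08:10:00,35.01,30.5,6.0\n"
        + "b,2021-01-01 08:00:00,35.0,30.51,0.0\n",
    )
    df = read_fix_table(p)
    assert len(df) == 3
    assert list(df.columns[:5]) == ["individual_id", "timestamp", "lon", "lat", "ground_speed"]
    assert df["timestamp"].is_monotonic_increasing or True  # sorted within individual
    assert (df.groupby("individual_id")["timestamp"].apply(lambda s: s.is_monotonic_increasing)).all()


def test_read_collapses_duplicate_id_timestamp(tmp_path, caplog):
    p = _write(
        tmp_path,
        CSV_HEADER
        + "a,2021-01-01 08:00:00,35.0,30.5,1.0\n"
        + "a,2021-01-01 08:00:00,35.5,30.9,2.0\n",
    )
    df = read_fix_table(p)
    assert len(df) == 1
    assert df.loc[0, "lon"] == 35.0  # first occurrence kept


def test_read_missing_speed_column_is_config_error(tmp_path):
    p = _write(tmp_path, "individual_id,timestamp,lon,lat\na,2021-01-01,35,30,\n")
    with pytest.raises(ConfigurationError, match="ground_speed"):
        read_fix_table(p)


def test_read_empty_inputs(tmp_path):
    with pytest.raises(EmptyInputError):
        read_fix_table(_write(tmp_path, "", name="zero.csv"))
    with pytest.raises(EmptyInputError):
        read_fix_table(_write(tmp_path, CSV_HEADER, name="header_only.csv"))


def test_read_movebank_dialect(tmp_path):
    p = _write(
        tmp_path,
        "individual-local-identifier,timestamp,location-long,location-lat,ground-speed\n"
        "J15w,2021-01-01 08:00:00,35.0,30.5,4.2\n",
    )
    df = read_fix_table(p)
    assert df.loc[0, "individual_id"] == "J15w"
    assert df.loc[0, "ground_speed"] == 4.2


def test_read_drops_unparseable_rows(tmp_path):
    p = _write(
        tmp_path,
        CSV_HEADER
        + "a,2021-01-01 08:00:00,35.0,30.5,1.0\n"
        + "a,2021-01-01 08:10:00,999.0,30.5,1.0\n"   # lon out of range
        + "a,not-a-time,35.0,30.5,1.0\n",
    )
    df = read_fix_table(p)
    assert len(df) == 1


# ---------------------------------------------------------------------------
# epoch binning
# ---------------------------------------------------------------------------


def _cfg():
    return fixture_config()


def test_same_slot_keeps_fix_nearest_midpoint():
    # slot 08:00-08:10 on day one; midpoint 08:05
    base = pd.Timestamp("2021-01-01")
    df = pd.DataFrame(
        {
            "individual_id": ["a", "a"],
            "timestamp": [base + pd.Timedelta("8h1m"), base + pd.Timedelta("8h6m")],
            "lon": [35.0, 35.1],
            "lat": [30.5, 30.5],
            "ground_speed": [1.0, 2.0],
        }
    )
    out = bin_to_epochs(df, _cfg())
    assert len(out) == 1
    assert out.loc[0, "lon"] == 35.1  # 08:06 is nearer 08:05 than 08:01


def test_adjacent_slots_kept():
    base = pd.Timestamp("2021-01-01")
    df = pd.DataFrame(
        {
            "individual_id": ["a", "a"],
            "timestamp": [base + pd.Timedelta("8h1m"), base + pd.Timedelta("8h11m")],
            "lon": [35.0, 35.1],
            "lat": [30.5, 30.5],
            "ground_speed": [1.0, 2.0],
        }
    )
    out = bin_to_epochs(df, _cfg())
    assert len(out) == 2
    assert sorted(out["epoch"]) == [48, 49]  # 8h = 48 ten-minute slots


def test_simultaneous_sampling_in_one_slot():
    base = pd.Timestamp("2021-01-01")
    df = pd.DataFrame(
        {
            "individual_id": ["A", "B"],
            "timestamp": [base + pd.Timedelta("8h3m"), base + pd.Timedelta("8h7m")],
            "lon": [35.0, 35.0],
            "lat": [30.5, 30.5],
            "ground_speed": [1.0, 1.0],
        }
    )
    out = bin_to_epochs(df, _cfg())
    assert out["epoch"].nunique() == 1  # both fall in the 08:00 slot


def test_slot_pairing_is_subset_of_delta_t_pairing(rng):
    """Fixed-slot simultaneity is conservative: any co-slotted pair of
    fixes is also within one interval of each other in raw time (the
    converse can fail across a slot boundary, e.g. 08:09 vs 08:11)."""
    cfg = _cfg()
    base = pd.Timestamp("2021-01-01")
    for _ in range(20):
        rows = []
        for ind in ("A", "B"):
            times = np.sort(rng.choice(600, size=12, replace=False))
            for t in times:
                rows.append((ind, base + pd.Timedelta(minutes=int(t))))
        df = pd.DataFrame(rows, columns=["individual_id", "timestamp"])
        df["lon"], df["lat"], df["ground_speed"] = 35.0, 30.5, 1.0
        out = bin_to_epochs(df, cfg)
        a = out[out.individual_id == "A"].set_index("epoch")["timestamp"]
        b = out[out.individual_id == "B"].set_index("epoch")["timestamp"]
        shared = a.index.intersection(b.index)
        for slot in shared:
            assert abs(a[slot] - b[slot]) <= cfg.fix_interval


def test_binning_is_idempotent(small_sim):
    cfg = fixture_config()
    once = bin_to_epochs(small_sim.fixes.drop(columns="epoch"), cfg)
    twice = bin_to_epochs(once, cfg)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_haversine_identical_points_zero():
    assert great_circle_distance(35.0, 30.5, 35.0, 30.5) == 0.0


def test_haversine_one_degree_on_equator():
    # R * pi / 180 for one degree of longitude at the equator
    assert great_circle_distance(0.0, 0.0, 1.0, 0.0) == pytest.approx(111_195, abs=1)


def test_haversine_symmetry(rng):
    pts = rng.uniform([-180, -89], [180, 89], size=(100, 2))
    pts2 = rng.uniform([-180, -89], [180, 89], size=(100, 2))
    d1 = great_circle_distance(pts[:, 0], pts[:, 1], pts2[:, 0], pts2[:, 1])
    d2 = great_circle_distance(pts2[:, 0], pts2[:, 1], pts[:, 0], pts[:, 1])
    np.testing.assert_allclose(d1, d2, rtol=0, atol=1e-9)


@settings(max_examples=100, derandomize=True)
@given(
    st.tuples(*[st.floats(-179, 179) for _ in range(3)]),
    st.tuples(*[st.floats(-85, 85) for _ in range(3)]),
)
def test_haversine_triangle_inequality(lons, lats):
    a, b, c = [(lons[i], lats[i]) for i in range(3)]
    dab = great_circle_distance(*a, *b)
    dbc = great_circle_distance(*b, *c)
    dac = great_circle_distance(*a, *c)
    assert dac <= dab + dbc + 1e-6 * max(dac, 1.0)


def test_point_in_polygon_conventions():
    poly = square_polygon(BASE_LON, BASE_LAT, half_m=30)
    assert point_in_polygon(poly.centroid.x, poly.centroid.y, poly)
    far_lon, far_lat = offset_lonlat(10_000, 0)
    assert not point_in_polygon(far_lon, far_lat, poly)
    vx, vy = poly.exterior.coords[0]
    assert point_in_polygon(vx, vy, poly)  # boundary counts as inside


def test_roost_geojson_roundtrip(tmp_path):
    roosts = {"R1": square_polygon(BASE_LON, BASE_LAT, 20), "R2": square_polygon(BASE_LON + 0.1, BASE_LAT, 25)}
    path = tmp_path / "roosts.geojson"
    write_roost_polygons(roosts, path)
    back = load_roost_polygons(path)
    assert set(back) == {"R1", "R2"}
    assert back["R1"].equals_exact(roosts["R1"], tolerance=1e-12)
    assert polygon_area_m2(back["R1"]) == pytest.approx(40 * 40, rel=0.01)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------


def _daily_track(ind, n_days, dx_m=0.0, start="2021-01-02"):
    base = pd.Timestamp(start)
    rows = []
    for d in range(n_days):
        lon, lat = offset_lonlat(dx_m, 0)
        rows.append((ind, base + pd.Timedelta(days=d, hours=8), lon, lat, 1.0))
    return rows


def test_filter_duration_and_range():
    cfg = fixture_config(min_tracking_days=71, max_range_km=400)
    rows = (
        _daily_track("short", 60)                 # 60 days -> excluded (duration)
        + _daily_track("good", 100)               # retained
        + _daily_track("wanderer", 100)
    )
    # one excursion beyond 400 km disqualifies outright
    far_lon, far_lat = offset_lonlat(450_000, 0)
    rows.append(("wanderer", pd.Timestamp("2021-04-20 08:00"), far_lon, far_lat, 1.0))
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    retained, report = filter_individuals(df, cfg)
    assert set(retained["individual_id"]) == {"good"}
    reasons = dict(zip(report["individual_id"], report["reason"]))
    assert reasons == {"short": "duration", "wanderer": "range"}


def test_filter_boundary_is_strict():
    # exactly 71 tracking days is NOT enough (> 71 required)
    cfg = fixture_config(min_tracking_days=71)
    df = pd.DataFrame(_daily_track("edge", 71), columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    retained, report = filter_individuals(df, cfg)
    assert retained.empty
    df72 = pd.DataFrame(_daily_track("edge", 72), columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    retained, _ = filter_individuals(df72, cfg)
    assert set(retained["individual_id"]) == {"edge"}


def test_filter_order_independent(rng):
    cfg = fixture_config(min_tracking_days=5)
    rows = _daily_track("a", 10) + _daily_track("b", 3) + _daily_track("c", 8)
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    r1, _ = filter_individuals(df, cfg)
    r2, _ = filter_individuals(shuffled, cfg)
    assert set(r1["individual_id"]) == set(r2["individual_id"]) == {"a", "c"}


def test_filter_respects_season_window():
    cfg = fixture_config(min_tracking_days=5, season_start="2021-01-01", season_end="2021-02-01")
    rows = _daily_track("a", 10, start="2021-01-02") + _daily_track("b", 40, start="2021-03-01")
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    retained, report = filter_individuals(df, cfg)
    assert set(retained["individual_id"]) == {"a"}  # b's fixes fall outside the season


def test_config_validation():
    with pytest.raises(ConfigurationError):
        StudyConfig(flight_speed_threshold=0)
    with pytest.raises(ConfigurationError):
        StudyConfig(season_start=dt.date(2021, 6, 1), season_end=dt.date(2021, 1, 1))
    with pytest.raises(ConfigurationError):
        StudyConfig(coflight_distance=-1)
    StudyConfig(coflight_distance=0)  # zero annihilates the layer but is legal
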