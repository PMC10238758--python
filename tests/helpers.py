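"""Shared fixture builders and brute-force oracles for the test suite.

The oracles deliberately use naive pure-Python enumeration (triple loops
over pairs and slots) so they stay independent of the vectorized
detection code they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from vulturenet.trajectory import EARTH_RADIUS_M, StudyConfig, great_circle_distance, point_in_polygon

BASE_LON, BASE_LAT = 35.0, 30.5
M_PER_DEG_LAT = math.radians(1.0) * EARTH_RADIUS_M
M_PER_DEG_LON = M_PER_DEG_LAT * math.cos(math.radians(BASE_LAT))


def offset_lonlat(dx_m: float, dy_m: float, lon0: float = BASE_LON, lat0: float = BASE_LAT):
    return lon0 + dx_m / M_PER_DEG_LON, lat0 + dy_m / M_PER_DEG_LAT


def square_polygon(lon: float, lat: float, half_m: float = 30.0) -> Polygon:
    dx = half_m / M_PER_DEG_LON
    dy = half_m / M_PER_DEG_LAT
    return Polygon(
        [(lon - dx, lat - dy), (lon + dx, lat - dy), (lon + dx, lat + dy), (lon - dx, lat + dy)]
    )


def fixes_from_rows(rows) -> pd.DataFrame:
    """Rows of (individual_id, epoch, dx_m, dy_m, ground_speed)."""
    recs = []
    for ind, epoch, dx, dy, speed in rows:
        lon, lat = offset_lonlat(dx, dy)
        recs.append(
            {
                "individual_id": ind,
                "timestamp": pd.Timestamp("2021-01-01") + pd.Timedelta(minutes=10 * epoch),
                "lon": lon,
                "lat": lat,
                "ground_speed": float(speed),
                "epoch": int(epoch),
            }
        )
    return pd.DataFrame(recs)


def fixture_config(**overrides) -> StudyConfig:
    defaults = dict(
        season_start="2021-01-01",
        season_end="2021-06-01",
        tagging_site=(BASE_LON, BASE_LAT),
    )
    defaults.update(overrides)
    return StudyConfig.from_dict(defaults)


def random_fixture(rng: np.random.Generator, max_individuals: int = 6, max_slots: int = 50):
    """A random small epoch-aligned fix table with positions clustered
    around a few hotspots so distances straddle both the 50 m and the
    1000 m thresholds, mixed flight/ground speeds (including exactly
    5.0 m/s), and random missing fixes."""
    n_ind = int(rng.integers(2, max_individuals + 1))
    n_slots = int(rng.integers(4, max_slots + 1))
    hotspots = [(0.0, 0.0), (30.0, 20.0), (700.0, 100.0), (5000.0, -2000.0)]
    rows = []
    for k in range(n_ind):
        ind = f"A{k}"
        for slot in range(n_slots):
            if rng.random() < 0.15:
                continue  # missing fix
            hx, hy = hotspots[int(rng.integers(len(hotspots)))]
            dx = hx + rng.uniform(-40, 40)
            dy = hy + rng.uniform(-40, 40)
            speed = float(rng.choice([0.0, 1.0, 3.0, 5.0, 5.1, 8.0, 12.0]))
            rows.append((ind, slot, dx, dy, speed))
    return fixes_from_rows(rows)


def brute_force_events(df: pd.DataFrame, cfg: StudyConfig, situation: str, roosts=None):
    """All-pairs all-runs enumeration of proximity events, one slot at a time."""
    flying = situation == "coflight"
    limit = cfg.coflight_distance if flying else cfg.ground_distance
    ids = sorted(df["individual_id"].unique())
    by_key = {
        (r.individual_id, r.epoch): r for r in df.itertuples(index=False)
    }
    n_slots = int(df["epoch"].max()) + 1 if len(df) else 0
    events = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            run_start = None
            for slot in range(n_slots + 1):
                ok = False
                if slot < n_slots:
                    fa = by_key.get((ids[i], slot))
                    fb = by_key.get((ids[j], slot))
                    if fa is not None and fb is not None:
                        sa = fa.ground_speed > cfg.flight_speed_threshold
                        sb = fb.ground_speed > cfg.flight_speed_threshold
                        state = (sa and sb) if flying else (not sa and not sb)
                        if state:
                            d = great_circle_distance(fa.lon, fa.lat, fb.lon, fb.lat)
                            ok = d <= limit
                            if ok and roosts is not None:
                                for f in (fa, fb):
                                    if any(point_in_polygon(f.lon, f.lat, p) for p in roosts.values()):
                                        ok = False
                                        break
                if ok and run_start is None:
                    run_start = slot
                elif not ok and run_start is not None:
                    n_ep = slot - run_start
                    if n_ep >= cfg.min_consecutive_fixes:
                        events.append((ids[i], ids[j], situation, run_start, slot - 1, n_ep))
                    run_start = None
    return sorted(events)


def event_tuples(events: pd.DataFrame):
    return sorted(
        (r.id_a, r.id_b, r.situation, int(r.start), int(r.end), int(r.n_epochs))
        for r in events.itertuples(index=False)
    )


def brute_force_joint_counts(df: pd.DataFrame):
    """Double-loop joint sampling denominators over epoch slots."""
    ids = sorted(df["individual_id"].unique())
    slots_of = {
        ind: set(grp["epoch"]) for ind, grp in df.groupby("individual_id")
    }
    out = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            out[(ids[i], ids[j])] = len(slots_of[ids[i]] & slots_of[ids[j]])
    return out
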