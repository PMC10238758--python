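"""Pairwise interaction inference in three ecological situations.

From an epoch-aligned fix table we detect, for every unordered pair of
individuals:

* **co-flight** — both flying (ground speed strictly above the 5 m/s
  threshold) within 1000 m of each other for at least two consecutive
  epoch slots;
* **diurnal ground** — both on the ground within 50 m for at least two
  consecutive slots, excluding any slot where either fix lies inside a
  known roost polygon;
* **nocturnal ground** — co-occupancy of the same roost polygon
  overnight, with nightly roost assignment from the last evening fix,
  else the first fix of the next morning, else the midpoint of those two
  positions.

A slot where either individual lacks a fix breaks a consecutive run; no
gap bridging is performed.  Events are symmetric in pair order and
deterministic given the inputs.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConsistencyError
from .trajectory import (
    StudyConfig,
    great_circle_distance,
    point_in_polygon,
    points_in_any_polygon,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

EVENT_COLUMNS = ["id_a", "id_b", "situation", "start", "end", "n_epochs"]
ASSIGNMENT_COLUMNS = ["individual_id", "night_date", "roost_id", "method"]


class Situation(str, enum.Enum):
    COFLIGHT = "coflight"
    NOCTURNAL_GROUND = "nocturnal"
    DIURNAL_GROUND = "diurnal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SITUATIONS = (Situation.COFLIGHT, Situation.NOCTURNAL_GROUND, Situation.DIURNAL_GROUND)


class AssignmentMethod(str, enum.Enum):
    LAST_FIX = "LAST_FIX"
    FIRST_FIX = "FIRST_FIX"
    MIDPOINT = "MIDPOINT"
    NONE = "NONE"


def classify_flight(speed: float, threshold: float = 5.0) -> bool:
    """True iff flying: speed strictly greater than the threshold.

    Equality is left on the ground side ("faster than" / "slower than"
    are both strict).
    """
    if speed < 0:
        raise ValueError(f"ground speed must be non-negative, got {speed}")
    return speed > threshold


# ---------------------------------------------------------------------------
# slot-grid machinery
# ---------------------------------------------------------------------------

def _slot_grids(
    df: pd.DataFrame, ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Dense (n_individuals, n_slots) grids of lon/lat/speed and presence."""
    if "epoch" not in df.columns:
        raise ValueError("fix table must be epoch-aligned (run bin_to_epochs first)")
    n = len(ids)
    n_slots = int(df["epoch"].max()) + 1 if len(df) else 0
    lon = np.full((n, n_slots), np.nan)
    lat = np.full((n, n_slots), np.nan)
    speed = np.full((n, n_slots), np.nan)
    index = {ind: k for k, ind in enumerate(ids)}
    rows = df["individual_id"].map(index).to_numpy()
    cols = df["epoch"].to_numpy()
    lon[rows, cols] = df["lon"].to_numpy()
    lat[rows, cols] = df["lat"].to_numpy()
    speed[rows, cols] = df["ground_speed"].to_numpy()
    present = ~np.isnan(speed)
    return lon, lat, speed, present, n_slots


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive slot indices."""
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _detect_proximity_events(
    df: pd.DataFrame,
    cfg: StudyConfig,
    situation: Situation,
    max_distance: float,
    flying: bool,
    roosts: Mapping[str, Polygon] | None = None,
) -> pd.DataFrame:
    ids = sorted(df["individual_id"].unique())
    lon, lat, speed, present, n_slots = _slot_grids(df, ids)
    if n_slots == 0 or len(ids) < 2:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    with np.errstate(invalid="ignore"):
        is_flying = speed > cfg.flight_speed_threshold
    state_ok = is_flying if flying else (~is_flying & present)

    in_roost = np.zeros_like(present)
    if roosts:
        flat = present.ravel()
        in_flat = np.zeros(flat.shape, dtype=bool)
        in_flat[flat] = points_in_any_polygon(
            lon.ravel()[flat], lat.ravel()[flat], list(roosts.values())
        )
        in_roost = in_flat.reshape(present.shape)

    records: list[tuple] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = present[i] & present[j] & state_ok[i] & state_ok[j]
            if roosts is not None:
                both &= ~(in_roost[i] | in_roost[j])
            if not both.any():
                continue
            dist = great_circle_distance(lon[i], lat[i], lon[j], lat[j])
            ok = both & (np.nan_to_num(dist, nan=np.inf) <= max_distance)
            for start, end in _runs(ok):
                n_ep = end - start + 1
                if n_ep >= cfg.min_consecutive_fixes:
                    records.append((ids[i], ids[j], situation.value, start, end, n_ep))
    return pd.DataFrame(records, columns=EVENT_COLUMNS)


def detect_coflight_events(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Co-flight events: both flying within ``cfg.coflight_distance`` for
    at least ``cfg.min_consecutive_fixes`` consecutive slots."""
    return _detect_proximity_events(
        df, cfg, Situation.COFLIGHT, cfg.coflight_distance, flying=True
    )


def detect_diurnal_ground_events(
    df: pd.DataFrame, roosts: Mapping[str, Polygon], cfg: StudyConfig
) -> pd.DataFrame:
    """Diurnal ground events: both on the ground within
    ``cfg.ground_distance`` for at least ``cfg.min_consecutive_fixes``
    consecutive slots, with any in-roost slot disqualified."""
    return _detect_proximity_events(
        df, cfg, Situation.DIURNAL_GROUND, cfg.ground_distance, flying=False, roosts=roosts
    )


# ---------------------------------------------------------------------------
# nocturnal: roost assignment and co-occupancy
# ---------------------------------------------------------------------------

def _find_roost(lon: float, lat: float, roosts: Mapping[str, Polygon]) -> str | None:
    for rid, poly in roosts.items():
        if point_in_polygon(lon, lat, poly):
            return rid
    return None


def assign_roosts(
    df: pd.DataFrame, roosts: Mapping[str, Polygon], cfg: StudyConfig
) -> pd.DataFrame:
    """Nightly roost assignment per individual.

    The night labelled with date *d* spans the evening of *d* and the
    following morning.  Branch priority: last fix of day *d* inside a
    polygon (LAST_FIX), else first fix of day *d+1* (FIRST_FIX), else
    the midpoint of those two positions (MIDPOINT); otherwise the night
    is UNASSIGNED (NONE).  One row per (individual, night) for which at
    least one of the two anchor fixes exists.
    """
    records: list[tuple] = []
    day = df["timestamp"].dt.normalize()
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        days = day.loc[grp.index]
        last_of_day = grp.groupby(days.values).last()
        first_of_day = grp.groupby(days.values).first()
        nights = sorted(
            set(last_of_day.index) | {d - pd.Timedelta(days=1) for d in first_of_day.index}
        )
        for night in nights:
            evening = last_of_day.loc[night] if night in last_of_day.index else None
            nxt = night + pd.Timedelta(days=1)
            morning = first_of_day.loc[nxt] if nxt in first_of_day.index else None
            if evening is None and morning is None:
                continue
            roost_id, method = UNASSIGNED, AssignmentMethod.NONE
            if evening is not None:
                rid = _find_roost(evening["lon"], evening["lat"], roosts)
                if rid is not None:
                    roost_id, method = rid, AssignmentMethod.LAST_FIX
            if method is AssignmentMethod.NONE and morning is not None:
                rid = _find_roost(morning["lon"], morning["lat"], roosts)
                if rid is not None:
                    roost_id, method = rid, AssignmentMethod.FIRST_FIX
            if method is AssignmentMethod.NONE and evening is not None and morning is not None:
                mid_lon = (evening["lon"] + morning["lon"]) / 2.0
                mid_lat = (evening["lat"] + morning["lat"]) / 2.0
                rid = _find_roost(mid_lon, mid_lat, roosts)
                if rid is not None:
                    roost_id, method = rid, AssignmentMethod.MIDPOINT
            records.append((ind, night.date(), roost_id, method.value))
    return pd.DataFrame(records, columns=ASSIGNMENT_COLUMNS)


def nocturnal_cooccurrences(assignments: pd.DataFrame) -> pd.DataFrame:
    """One NOCTURNAL_GROUND event per night per unordered pair sharing a roost."""
    records: list[tuple] = []
    assigned = assignments[assignments["roost_id"] != UNASSIGNED]
    for (night, _rid), grp in assigned.groupby(["night_date", "roost_id"], sort=True):
        members = sorted(grp["individual_id"])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                records.append(
                    (members[i], members[j], Situation.NOCTURNAL_GROUND.value, night, night, 1)
                )
    return pd.DataFrame(records, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# joint-sampling denominators
# ---------------------------------------------------------------------------

def joint_sampling_counts(
    data: pd.DataFrame,
    situation: Situation | str,
    cohort: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise denominator matrix: sampling units in which both members
    of a pair were observed.

    For the diurnal situations (co-flight and diurnal ground) the unit is
    the epoch slot and ``data`` is the epoch-aligned fix table; for the
    nocturnal situation the unit is the night and ``data`` is the roost
    assignment table (only nights with an actual roost assignment count).
    Returns a symmetric integer DataFrame with zero diagonal, indexed by
    the cohort.
    """
    situation = Situation(situation)
    if situation is Situation.NOCTURNAL_GROUND:
        valid = data[data["roost_id"] != UNASSIGNED]
        unit_col, id_col = "night_date", "individual_id"
    else:
        valid = data
        unit_col, id_col = "epoch", "individual_id"
    ids = sorted(cohort) if cohort is not None else sorted(valid[id_col].unique())
    index = {ind: k for k, ind in enumerate(ids)}
    units = pd.unique(valid[unit_col])
    unit_index = {u: k for k, u in enumerate(units)}
    presence = np.zeros((len(ids), len(units)), dtype=bool)
    rows = valid[id_col].map(index)
    keep = rows.notna().to_numpy()
    presence[rows[keep].astype(int).to_numpy(), valid[unit_col].map(unit_index).to_numpy()[keep]] = True
    counts = presence.astype(np.int64) @ presence.T.astype(np.int64)
    np.fill_diagonal(counts, 0)
    return pd.DataFrame(counts, index=ids, columns=ids)


def together_counts(
    events: pd.DataFrame,
    cohort: Sequence[str],
    numerator: str = "slots",
) -> pd.DataFrame:
    """Pairwise numerator matrix from an event table.

    ``numerator="slots"`` sums ``n_epochs`` over a pair's events (slots
    in qualifying runs for diurnal situations, nights for the nocturnal
    one); ``numerator="events"`` counts events.
    """
    if numerator not in ("slots", "events"):
        raise ValueError("numerator must be 'slots' or 'events'")
    ids = sorted(cohort)
    index = {ind: k for k, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for row in events.itertuples(index=False):
        if row.id_a not in index or row.id_b not in index:
            raise ConsistencyError(f"event pair ({row.id_a}, {row.id_b}) outside cohort")
        a, b = index[row.id_a], index[row.id_b]
        inc = row.n_epochs if numerator == "slots" else 1
        counts[a, b] += inc
        counts[b, a] += inc
    return pd.DataFrame(counts, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# post-hoc verification (used by property tests and audits)
# ---------------------------------------------------------------------------

def verify_events(
    events: pd.DataFrame,
    df: pd.DataFrame,
    cfg: StudyConfig,
    roosts: Mapping[str, Polygon] | None = None,
) -> bool:
    """Re-check every diurnal-situation event slot against the raw fixes.

    Returns True iff, for every event and every slot it spans, both
    individuals have a fix, both are in the required behavioural state,
    the pairwise distance is within the situation threshold, and (for
    diurnal ground) neither fix lies inside a roost polygon.
    """
    fixes = df.set_index(["individual_id", "epoch"])
    for ev in events.itertuples(index=False):
        situation = Situation(ev.situation)
        if situation is Situation.NOCTURNAL_GROUND:
            continue
        limit = cfg.coflight_distance if situation is Situation.COFLIGHT else cfg.ground_distance
        want_flying = situation is Situation.COFLIGHT
        for slot in range(int(ev.start), int(ev.end) + 1):
            try:
                fa = fixes.loc[(ev.id_a, slot)]
                fb = fixes.loc[(ev.id_b, slot)]
            except KeyError:
                return False
            for f in (fa, fb):
                if classify_flight(f["ground_speed"], cfg.flight_speed_threshold) != want_flying:
                    return False
                if roosts is not None and situation is Situation.DIURNAL_GROUND:
                    if _find_roost(f["lon"], f["lat"], roosts) is not None:
                        return False
            if great_circle_distance(fa["lon"], fa["lat"], fb["lon"], fb["lat"]) > limit:
                return False
    return True
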