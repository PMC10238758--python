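"""Reading, validating, epoch-aligning and filtering GPS fix tables.

A *fix table* is a :class:`pandas.DataFrame` with one row per fix and the
canonical columns ``individual_id`` (str), ``timestamp`` (naive local
datetime), ``lon``/``lat`` (decimal degrees, WGS84), ``ground_speed``
(m/s) and optionally ``altitude`` (m).  After :func:`bin_to_epochs` the
table additionally carries an integer ``epoch`` column: the index of the
fix-interval slot since the start of the study season.  Two individuals
are *simultaneously sampled* in a slot iff both have a fix in it.

Roosts are named ground polygons (small, ~10**2-10**3 m**2); containment
tests are planar in lon/lat, which is exact far beyond GPS error at that
scale, while pairwise distances use the spherical haversine formula.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point, Polygon, mapping, shape

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: canonical column name -> Movebank export column name
MOVEBANK_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "ground_speed": "ground-speed",
    "altitude": "height-above-msl",
}

REQUIRED_COLUMNS = ("individual_id", "timestamp", "lon", "lat", "ground_speed")


def _parse_time(value) -> dt.time:
    if isinstance(value, dt.time):
        return value
    hh, mm = str(value).split(":")[:2]
    return dt.time(int(hh), int(mm))


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass
class StudyConfig:
    """Thresholds and study-window settings for interaction inference.

    Defaults are the study-system values: birds are classified as flying
    above 5 m/s; co-flight requires <= 1000 m separation and diurnal
    ground interaction <= 50 m, both for at least two consecutive 10-min
    fixes; individuals are retained only with more than 71 tracking days
    and no fix farther than 400 km from their tagging site.
    """

    flight_speed_threshold: float = 5.0      # m/s, strictly greater => flying
    coflight_distance: float = 1000.0        # m
    ground_distance: float = 50.0            # m
    min_consecutive_fixes: int = 2
    fix_interval_minutes: float = 10.0
    min_tracking_days: int = 71              # retained iff days > this
    max_range_km: float = 400.0              # retained iff all fixes within
    season_start: dt.date = dt.date(2020, 12, 1)
    season_end: dt.date = dt.date(2021, 6, 1)
    day_start: dt.time = dt.time(6, 0)       # local clock day window
    day_end: dt.time = dt.time(18, 0)
    #: single (lon, lat) shared tagging site, or mapping individual_id -> (lon, lat)
    tagging_site: tuple[float, float] | Mapping[str, tuple[float, float]] | None = None
    #: SRI numerator unit for diurnal situations: "slots" or "events"
    sri_numerator: str = "slots"

    def __post_init__(self) -> None:
        self.day_start = _parse_time(self.day_start)
        self.day_end = _parse_time(self.day_end)
        self.season_start = _parse_date(self.season_start)
        self.season_end = _parse_date(self.season_end)
        for name in (
            "flight_speed_threshold",
            "min_consecutive_fixes",
            "fix_interval_minutes",
            "max_range_km",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        # distance thresholds may be zero (annihilates the layer, useful
        # for sensitivity analyses) but never negative
        for name in ("coflight_distance", "ground_distance"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.season_start >= self.season_end:
            raise ConfigurationError("season_start must precede season_end")
        if self.sri_numerator not in ("slots", "events"):
            raise ConfigurationError("sri_numerator must be 'slots' or 'events'")

    @property
    def fix_interval(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.fix_interval_minutes)

    @property
    def season_start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.season_start)

    @property
    def season_end_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.season_end)

    def site_for(self, individual_id: str) -> tuple[float, float]:
        """Tagging site for one individual (shared or per-individual)."""
        if self.tagging_site is None:
            raise ConfigurationError("tagging_site is not configured")
        if isinstance(self.tagging_site, Mapping):
            try:
                return tuple(self.tagging_site[individual_id])
            except KeyError as exc:
                raise ConfigurationError(
                    f"no tagging site for individual {individual_id!r}"
                ) from exc
        return tuple(self.tagging_site)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if not isinstance(v, Mapping)
        }
        d["season_start"] = self.season_start.isoformat()
        d["season_end"] = self.season_end.isoformat()
        d["day_start"] = self.day_start.strftime("%H:%M")
        d["day_end"] = self.day_end.strftime("%H:%M")
        if isinstance(self.tagging_site, Mapping):
            d["tagging_site"] = {k: list(v) for k, v in self.tagging_site.items()}
        elif self.tagging_site is not None:
            d["tagging_site"] = list(self.tagging_site)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        site = data.get("tagging_site")
        if isinstance(site, Mapping):
            data["tagging_site"] = {k: tuple(v) for k, v in site.items()}
        elif isinstance(site, (list, tuple)):
            data["tagging_site"] = tuple(site)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown study config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file with study/analysis/sim sections."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return data


# ---------------------------------------------------------------------------
# fix-table I/O
# ---------------------------------------------------------------------------

def read_fix_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a fix table from CSV/TSV into canonical columns.

    Column resolution, per canonical name: an explicit ``column_map``
    entry, else the canonical name itself, else the Movebank export
    name.  Duplicate (individual, timestamp) rows keep the first
    occurrence; rows with unparseable coordinates/timestamps are dropped
    and the count logged.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"fix table not found: {path}")
    try:
        raw = pd.read_csv(path, sep=sep, dtype={"individual_id": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"fix table {path} is empty") from exc
    if raw.empty:
        raise EmptyInputError(f"fix table {path} contains no rows")

    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canon in (*REQUIRED_COLUMNS, "altitude"):
        candidates = [column_map.get(canon), canon, MOVEBANK_COLUMNS[canon]]
        found = next((c for c in candidates if c is not None and c in raw.columns), None)
        if found is None:
            if canon == "altitude":
                continue
            raise ConfigurationError(
                f"required column {canon!r} not resolvable in {path.name}; "
                f"provide a column_map entry"
            )
        rename[found] = canon
    df = raw.rename(columns=rename)[list(rename.values())].copy()

    df["individual_id"] = df["individual_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    for col in ("lon", "lat", "ground_speed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        df["timestamp"].isna()
        | df["lon"].isna()
        | df["lat"].isna()
        | ~df["lon"].between(-180, 180)
        | ~df["lat"].between(-90, 90)
        | (df["ground_speed"] < 0)
        | df["ground_speed"].isna()
    )
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable/invalid fields from %s", n_bad, path.name)
    df = df[~bad]

    n_before = len(df)
    df = df.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("collapsed %d duplicate (individual, timestamp) rows", n_dup)
    if df.empty:
        raise EmptyInputError(f"fix table {path} contains no valid rows")
    return df.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def write_fix_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine distance in meters on a sphere of radius 6,371,000 m.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def point_in_polygon(lon: float, lat: float, polygon: Polygon) -> bool:
    """Planar even-odd containment in the lon/lat plane; boundary counts as inside."""
    return bool(shapely.covers(polygon, Point(lon, lat)))


def points_in_any_polygon(lon: np.ndarray, lat: np.ndarray, polygons: Sequence[Polygon]) -> np.ndarray:
    """Vectorized membership of points in the union of ``polygons`` (boundary inclusive)."""
    lon = np.asarray(lon, dtype=float)
    pts = shapely.points(lon, np.asarray(lat, dtype=float))
    inside = np.zeros(lon.shape, dtype=bool)
    for poly in polygons:
        shapely.prepare(poly)
        inside |= shapely.covers(poly, pts)
    return inside


def polygon_area_m2(polygon: Polygon) -> float:
    """Planar polygon area in m**2 via a local equirectangular scaling."""
    lat0 = polygon.centroid.y
    mx = np.radians(1.0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    my = np.radians(1.0) * EARTH_RADIUS_M
    x, y = polygon.exterior.coords.xy
    x = np.asarray(x) * mx
    y = np.asarray(y) * my
    return float(0.5 * abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])))


# ---------------------------------------------------------------------------
# roost polygons (GeoJSON)
# ---------------------------------------------------------------------------

def load_roost_polygons(path: str | Path) -> dict[str, Polygon]:
    """Read a GeoJSON FeatureCollection of roosts keyed by property ``roost_id``."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"roost polygon file not found: {path}")
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ConfigurationError("roost file must be a GeoJSON FeatureCollection")
    roosts: dict[str, Polygon] = {}
    for i, feature in enumerate(gj.get("features", [])):
        roost_id = str(feature.get("properties", {}).get("roost_id", f"roost_{i}"))
        geom = shape(feature["geometry"])
        if not isinstance(geom, Polygon) or not geom.is_valid or geom.area <= 0:
            raise ConfigurationError(f"roost {roost_id!r} is not a valid simple polygon")
        roosts[roost_id] = geom
    if not roosts:
        raise EmptyInputError(f"no roost polygons in {path}")
    return roosts


def write_roost_polygons(roosts: Mapping[str, Polygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"roost_id": rid, "area_m2": polygon_area_m2(poly)},
            "geometry": mapping(poly),
        }
        for rid, poly in roosts.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# epoch alignment and cohort filtering
# ---------------------------------------------------------------------------

def bin_to_epochs(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Assign each fix to a fixed wall-clock slot anchored at season start.

    ``epoch = floor((timestamp - season_start) / fix_interval)``.  When an
    individual has several fixes in one slot, the fix nearest the slot
    midpoint is kept, so afterwards each individual has at most one fix
    per slot.  Idempotent.
    """
    interval = cfg.fix_interval
    out = df.copy()
    delta = out["timestamp"] - cfg.season_start_ts
    out["epoch"] = (delta // interval).astype(np.int64)
    midpoint = cfg.season_start_ts + (out["epoch"] + 0.5) * interval
    out["_dist_mid"] = (out["timestamp"] - midpoint).abs()
    out = (
        out.sort_values(["individual_id", "epoch", "_dist_mid"], kind="mergesort")
        .drop_duplicates(subset=["individual_id", "epoch"], keep="first")
        .drop(columns="_dist_mid")
        .sort_values(["individual_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def filter_individuals(
    df: pd.DataFrame, cfg: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort filters; return (retained fixes, exclusion report).

    Fixes are first restricted to the season window.  An individual is
    retained iff (a) it has strictly more than ``min_tracking_days``
    distinct calendar days with at least one fix, and (b) none of its
    season fixes lies farther than ``max_range_km`` from its tagging
    site.  The report has one row per excluded individual with the
    reason and the offending quantity.
    """
    in_season = (df["timestamp"] >= cfg.season_start_ts) & (df["timestamp"] < cfg.season_end_ts)
    season = df[in_season]
    exclusions: list[dict] = []
    keep_ids: list[str] = []
    for ind, grp in season.groupby("individual_id", sort=True):
        n_days = grp["timestamp"].dt.normalize().nunique()
        if n_days <= cfg.min_tracking_days:
            exclusions.append(
                {"individual_id": ind, "reason": "duration", "value": float(n_days)}
            )
            continue
        site_lon, site_lat = cfg.site_for(ind)
        dist_km = great_circle_distance(grp["lon"].to_numpy(), grp["lat"].to_numpy(), site_lon, site_lat) / 1000.0
        max_km = float(np.max(dist_km))
        if max_km > cfg.max_range_km:
            exclusions.append({"individual_id": ind, "reason": "range", "value": max_km})
            continue
        keep_ids.append(ind)
    for ind in set(df["individual_id"]) - set(season["individual_id"]):
        exclusions.append({"individual_id": ind, "reason": "duration", "value": 0.0})
    report = pd.DataFrame(exclusions, columns=["individual_id", "reason", "value"])
    retained = season[season["individual_id"].isin(keep_ids)].reset_index(drop=True)
    if keep_ids:
        logger.info("retained %d individuals, excluded %d", len(keep_ids), len(report))
    return retained, report.sort_values("individual_id").reset_index(drop=True)
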