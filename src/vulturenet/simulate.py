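"""Agent-based generator of GPS fix tables with planted social structure.

The simulator emulates a population of tagged scavenging raptors over a
breeding season: every individual spends the night in a communal roost
polygon, departs after dawn, flies (8-20 m/s) toward the day's carcass
site in a co-flight group, feeds on the ground (0-2 m/s) in a tight
cluster near the carcass, and returns to a roost before dusk.  Fixes are
emitted on the regular 10-min grid inside the daytime window only, as
the tags do.

Three independent *planted* pairwise affinity matrices — one per
situation (co-flight, diurnal ground, nocturnal ground) — drive group
membership: each day/night, individuals are partitioned by a sequential
affinity-weighted aggregation process, so pairs with high affinity
co-occur often and the simple ratio index estimated by the pipeline is a
monotone readout of the planted affinity.  Every true co-occurrence is
logged, giving ground truth for detector recall/precision and for
parameter-recovery checks.

Movement between waypoints is linear interpolation at fix epochs; the
pipeline consumes positions and speeds per slot only, so kinematic
realism beyond speed classes is deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigurationError
from .interactions import Situation
from .trajectory import EARTH_RADIUS_M, StudyConfig, polygon_area_m2

M_PER_DEG_LAT = math.radians(1.0) * EARTH_RADIUS_M  # ~111,195 m


@dataclass
class SimConfig:
    """Study-scale defaults: 29 tagged individuals followed for 120 days
    at a 10-min diurnal fix interval, 6 communal roosts and 8 feeding
    sites inside a ~200 x 200 km region."""

    n_individuals: int = 29
    n_roosts: int = 6
    n_feeding_sites: int = 8
    n_days: int = 120
    fix_interval_minutes: float = 10.0
    day_start: dt.time = dt.time(6, 0)
    day_end: dt.time = dt.time(18, 0)
    flight_speed_range: tuple[float, float] = (8.0, 20.0)   # m/s
    ground_speed_range: tuple[float, float] = (0.0, 2.0)    # m/s
    #: probability that a day has an active carcass (feeding aggregation)
    feeding_event_rate: float = 1.0
    #: per-individual probability of attending the day's carcass
    attendance_prob: float = 0.85
    missing_fix_prob: float = 0.0
    rng_seed: int = 0
    season_start: dt.date = dt.date(2021, 1, 1)
    region_center: tuple[float, float] = (35.0, 30.5)       # lon, lat
    roost_core_km: float = 30.0      # roosts within +- this of the center
    site_core_km: float = 40.0       # feeding sites within +- this
    roost_area_mean_m2: float = 800.0
    roost_area_sigma_log: float = 1.3
    #: latent-space scale of the default affinities; smaller = more clustered
    affinity_tau: float = 0.15
    #: blending of a shared social space into each situation's latent space
    #: (0 = situations fully independent, 1 = one common structure); real
    #: populations sit in between: individuals that are social in one
    #: situation tend to be social in others
    social_alignment: float = 0.7
    #: group-formation weights: join weight = affinity_gain * sum(affinity to group)
    affinity_gain: float = 3.0
    new_group_weight: float = 1.0
    #: per-individual distribution over roosts (n_individuals x n_roosts); default built
    #: from a "home roost" one-hot mixed with 10% uniform
    roost_preference: np.ndarray | None = None
    #: planted symmetric pairwise affinity per situation label; defaults drawn
    #: from independent 2-D latent social spaces
    social_preference: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name in ("feeding_event_rate", "attendance_prob", "missing_fix_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_roosts < 1 or self.n_feeding_sites < 1:
            raise ConfigurationError("population, roost and site counts must be >= 1")
        if isinstance(self.day_start, str):
            hh, mm = self.day_start.split(":")[:2]
            self.day_start = dt.time(int(hh), int(mm))
        if isinstance(self.day_end, str):
            hh, mm = self.day_end.split(":")[:2]
            self.day_end = dt.time(int(hh), int(mm))
        if isinstance(self.season_start, str):
            self.season_start = dt.date.fromisoformat(self.season_start)
        if self.social_preference is not None:
            for name, mat in self.social_preference.items():
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (self.n_individuals, self.n_individuals):
                    raise ConfigurationError(f"affinity matrix {name} has wrong shape")
                if not np.allclose(mat, mat.T) or np.any(np.diag(mat) != 0):
                    raise ConfigurationError(
                        f"affinity matrix {name} must be symmetric with zero diagonal"
                    )

    @property
    def slots_per_day(self) -> int:
        minutes = (
            self.day_end.hour * 60 + self.day_end.minute
            - self.day_start.hour * 60 - self.day_start.minute
        )
        return int(minutes // self.fix_interval_minutes)

    @property
    def epochs_per_day(self) -> int:
        return int(24 * 60 // self.fix_interval_minutes)

    @property
    def day_start_offset(self) -> int:
        return int(
            (self.day_start.hour * 60 + self.day_start.minute) // self.fix_interval_minutes
        )

    def individual_ids(self) -> list[str]:
        width = len(str(self.n_individuals))
        return [f"V{i + 1:0{width}d}" for i in range(self.n_individuals)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["day_start"] = self.day_start.strftime("%H:%M")
        d["day_end"] = self.day_end.strftime("%H:%M")
        d["season_start"] = self.season_start.isoformat()
        d["roost_preference"] = None if self.roost_preference is None else np.asarray(self.roost_preference).tolist()
        if self.social_preference is not None:
            d["social_preference"] = {k: np.asarray(v).tolist() for k, v in self.social_preference.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        if data.get("roost_preference") is not None:
            data["roost_preference"] = np.asarray(data["roost_preference"], dtype=float)
        if data.get("social_preference") is not None:
            data["social_preference"] = {
                k: np.asarray(v, dtype=float) for k, v in data["social_preference"].items()
            }
        if "flight_speed_range" in data:
            data["flight_speed_range"] = tuple(data["flight_speed_range"])
        if "ground_speed_range" in data:
            data["ground_speed_range"] = tuple(data["ground_speed_range"])
        if "region_center" in data:
            data["region_center"] = tuple(data["region_center"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown sim config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted structure and the realized co-occurrences it produced."""

    ids: list[str]
    #: situation label -> planted symmetric affinity matrix
    affinity: dict[str, np.ndarray]
    #: realized co-occurrence bouts: situation, id_a, id_b, day, n_epochs
    events: pd.DataFrame
    home_roost: np.ndarray | None = None

    def pair_totals(self, situation: Situation | str) -> pd.DataFrame:
        """Total true co-occurrence units per unordered pair (symmetric matrix)."""
        label = Situation(situation).value
        idx = {ind: k for k, ind in enumerate(self.ids)}
        mat = np.zeros((len(self.ids), len(self.ids)))
        sub = self.events[self.events["situation"] == label]
        for row in sub.itertuples(index=False):
            a, b = idx[row.id_a], idx[row.id_b]
            mat[a, b] += row.n_epochs
            mat[b, a] += row.n_epochs
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out_dir / "truth_events.csv", index=False)
        for name, mat in self.affinity.items():
            pd.DataFrame(mat, index=self.ids, columns=self.ids).to_csv(
                out_dir / f"truth_affinity_{name}.csv"
            )


@dataclass
class SimResult:
    fixes: pd.DataFrame
    roosts: dict[str, Polygon]
    feeding_sites: np.ndarray       # (n_sites, 2) lon/lat
    truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# geometry helpers (local flat-earth scaling around the study region)
# ---------------------------------------------------------------------------

def _m_per_deg_lon(lat: float) -> float:
    return M_PER_DEG_LAT * math.cos(math.radians(lat))


def _km_offset(center: np.ndarray, dx_km: float, dy_km: float, lat0: float) -> np.ndarray:
    return np.array(
        [center[0] + dx_km * 1000.0 / _m_per_deg_lon(lat0), center[1] + dy_km * 1000.0 / M_PER_DEG_LAT]
    )


def _convex_roost_polygon(center: np.ndarray, area_m2: float, lat0: float, rng: np.random.Generator) -> Polygon:
    # vertices on a circle in angular order => convex; near-regular spacing
    # keeps the apothem large so jittered points near the centroid stay inside
    angles = np.sort((np.arange(8) + rng.uniform(-0.2, 0.2, size=8)) * (2 * np.pi / 8))
    x = np.cos(angles)
    y = np.sin(angles)
    raw_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    scale = math.sqrt(area_m2 / raw_area)
    lon = center[0] + x * scale / _m_per_deg_lon(lat0)
    lat = center[1] + y * scale / M_PER_DEG_LAT
    return Polygon(zip(lon, lat))


def generate_landscape(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, Polygon], np.ndarray]:
    """Roost polygons (areas lognormal around the configured mean) and
    feeding-site coordinates, mutually separated by at least 2 km."""
    lat0 = cfg.region_center[1]
    center = np.asarray(cfg.region_center, dtype=float)

    def _scatter(n: int, half_km: float, existing: list[np.ndarray]) -> list[np.ndarray]:
        points: list[np.ndarray] = []
        attempts = 0
        while len(points) < n:
            attempts += 1
            if attempts > 10_000:
                raise ConfigurationError("cannot place landscape points 2 km apart; enlarge region")
            p = _km_offset(center, rng.uniform(-half_km, half_km), rng.uniform(-half_km, half_km), lat0)
            ok = all(
                _planar_dist_m(p, q, lat0) > 2_000.0 for q in [*existing, *points]
            )
            if ok:
                points.append(p)
        return points

    roost_centers = _scatter(cfg.n_roosts, cfg.roost_core_km, [])
    sites = _scatter(cfg.n_feeding_sites, cfg.site_core_km, roost_centers)

    sigma = cfg.roost_area_sigma_log
    mu = math.log(cfg.roost_area_mean_m2) - sigma**2 / 2.0
    areas = rng.lognormal(mu, sigma, size=cfg.n_roosts)
    roosts = {
        f"R{k + 1:02d}": _convex_roost_polygon(roost_centers[k], areas[k], lat0, rng)
        for k in range(cfg.n_roosts)
    }
    return roosts, np.asarray(sites)


def _planar_dist_m(p: np.ndarray, q: np.ndarray, lat0: float) -> float:
    dx = (p[0] - q[0]) * _m_per_deg_lon(lat0)
    dy = (p[1] - q[1]) * M_PER_DEG_LAT
    return math.hypot(dx, dy)


# ---------------------------------------------------------------------------
# planted social structure
# ---------------------------------------------------------------------------

def latent_affinities(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Default planted affinities from 2-D latent social spaces,
    affinity = exp(-distance / tau).

    Each situation's space is a blend of a shared population-wide space
    and a situation-specific one, weighted by ``cfg.social_alignment``,
    so social positions are partially (not fully) carried across
    situations — the regime the multilayer comparison is designed to
    quantify.
    """
    a_mix = float(cfg.social_alignment)
    # normalized blend: keeps the pairwise-distance scale (and with it the
    # strength of the planted within-situation signal) independent of the
    # alignment level
    norm = math.sqrt(a_mix**2 + (1.0 - a_mix) ** 2)
    z_shared = rng.uniform(0, 1, size=(cfg.n_individuals, 2))
    out: dict[str, np.ndarray] = {}
    for situation in Situation:
        z_own = rng.uniform(0, 1, size=(cfg.n_individuals, 2))
        z = (a_mix * z_shared + (1.0 - a_mix) * z_own) / norm
        d = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))
        a = np.exp(-d / cfg.affinity_tau)
        np.fill_diagonal(a, 0.0)
        out[situation.value] = a
    return out


def affinity_partition(
    members: np.ndarray,
    affinity: np.ndarray,
    rng: np.random.Generator,
    gain: float,
    new_group_weight: float,
) -> list[list[int]]:
    """Sequential affinity-weighted aggregation into groups.

    Individuals are visited in random order; each joins an existing
    group with weight ``gain * sum(affinity to its members)`` or opens a
    new group with weight ``new_group_weight * prod(1 - affinity to
    already-placed individuals)``.  With zero affinities everyone ends
    up alone; an affinity of exactly 1 forces the pair together.
    """
    order = rng.permutation(members)
    groups: list[list[int]] = []
    placed: list[int] = []
    for i in order:
        solo = new_group_weight * float(np.prod(1.0 - affinity[i, placed])) if placed else new_group_weight
        weights = np.array([gain * affinity[i, g].sum() for g in groups] + [solo])
        total = weights.sum()
        if total <= 0:
            choice = len(groups)
        else:
            choice = rng.choice(len(weights), p=weights / total)
        if choice == len(groups):
            groups.append([int(i)])
        else:
            groups[choice].append(int(i))
        placed.append(int(i))
    return groups


def _assign_groups_to_roosts(
    groups: list[list[int]],
    preference: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    """Each group draws a roost weighted by its members' preferences,
    without replacement while unused roosts remain (communal roosts are
    shared only when there are more groups than roosts)."""
    n_roosts = preference.shape[1]
    available = set(range(n_roosts))
    result = [0] * len(groups)
    for g in rng.permutation(len(groups)):
        pref = preference[groups[g]].sum(axis=0) + 1e-9
        pool = sorted(available) if available else list(range(n_roosts))
        w = pref[pool]
        roost = int(rng.choice(pool, p=w / w.sum()))
        result[g] = roost
        available.discard(roost)
    return result


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _leg_n_slots(dist_m: float, v_range: tuple[float, float], interval_s: float,
                 max_slots: int, rng: np.random.Generator) -> int:
    n_min = max(1, math.ceil(dist_m / (v_range[1] * interval_s)))
    n_max = max(n_min, math.floor(dist_m / (v_range[0] * interval_s)))
    n = int(rng.integers(n_min, min(n_max, n_min + 3) + 1))
    return min(n, max_slots) if max_slots >= 1 else n


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full season; returns fixes (complete sampling on the
    daytime grid), the landscape, and the ground truth.  Apply
    :func:`degrade` afterwards for missing fixes."""
    rng = np.random.default_rng(cfg.rng_seed)
    ids = cfg.individual_ids()
    n = cfg.n_individuals
    interval_s = cfg.fix_interval_minutes * 60.0
    spd = cfg.slots_per_day
    lat0 = cfg.region_center[1]
    m_lon, m_lat = _m_per_deg_lon(lat0), M_PER_DEG_LAT

    roosts, sites = generate_landscape(cfg, rng)
    roost_ids = list(roosts)
    roost_centers = np.array([[p.centroid.x, p.centroid.y] for p in roosts.values()])
    roost_radius_m = np.array(
        [math.sqrt(polygon_area_m2(p) / math.pi) for p in roosts.values()]
    )

    affinity = (
        {Situation(k).value: np.asarray(v, dtype=float) for k, v in cfg.social_preference.items()}
        if cfg.social_preference is not None
        else latent_affinities(cfg, rng)
    )
    for s in Situation:
        if s.value not in affinity:
            raise ConfigurationError(f"missing affinity matrix for situation {s.value!r}")

    if cfg.roost_preference is not None:
        preference = np.asarray(cfg.roost_preference, dtype=float)
        if preference.shape != (n, cfg.n_roosts):
            raise ConfigurationError("roost_preference must be (n_individuals, n_roosts)")
        home = preference.argmax(axis=1)
    else:
        # home roosts follow the nocturnal latent structure: highly
        # affine pairs prefer the same roost
        anchors = rng.uniform(0, 1, size=(cfg.n_roosts, 2))
        scores = affinity[Situation.NOCTURNAL_GROUND.value] + np.eye(n)
        seed_ind = rng.permutation(n)[: cfg.n_roosts]
        home = scores[:, seed_ind].argmax(axis=1) % cfg.n_roosts
        preference = np.full((n, cfg.n_roosts), 0.1 / cfg.n_roosts)
        preference[np.arange(n), home] += 0.9

    def roost_point(r: int) -> np.ndarray:
        jit = rng.uniform(-1, 1, size=2) * roost_radius_m[r] * 0.3
        return roost_centers[r] + np.array([jit[0] / m_lon, jit[1] / m_lat])

    def ground_speed(size=None):
        return rng.uniform(*cfg.ground_speed_range, size=size)

    all_lon, all_lat, all_speed, all_epoch, all_ind = [], [], [], [], []
    truth_rows: list[tuple] = []

    # the pre-season night (revealed by the first morning's fixes) follows
    # the same grouping mechanism as every other night; logged as day -1
    init_groups = affinity_partition(
        np.arange(n), affinity[Situation.NOCTURNAL_GROUND.value], rng,
        cfg.affinity_gain, cfg.new_group_weight,
    )
    init_roost = _assign_groups_to_roosts(init_groups, preference, rng)
    current_roost = np.zeros(n, dtype=int)
    for g, grp in enumerate(init_groups):
        for i in grp:
            current_roost[i] = init_roost[g]
    for r in range(cfg.n_roosts):
        members = sorted(np.flatnonzero(current_roost == r))
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                truth_rows.append(
                    (Situation.NOCTURNAL_GROUND.value, ids[members[x]], ids[members[y]], -1, 1)
                )

    for day in range(cfg.n_days):
        lon = np.full((n, spd), np.nan)
        lat = np.full((n, spd), np.nan)
        speed = np.full((n, spd), np.nan)
        p0 = np.array([roost_point(current_roost[i]) for i in range(n)])

        carcass_day = rng.random() < cfg.feeding_event_rate
        attend = (rng.random(n) < cfg.attendance_prob) if carcass_day else np.zeros(n, dtype=bool)
        attendees = np.flatnonzero(attend)
        loiterers = np.flatnonzero(~attend)

        depart_feed = np.full(n, spd - 10)  # evening departure slot, refined below
        day_pos = np.zeros((n, 2))          # daytime stationary point (cluster / loiter)
        arrive_feed = np.full(n, 10)

        if attendees.size:
            carcass = sites[int(rng.integers(len(sites)))]
            cf_groups = affinity_partition(
                attendees, affinity[Situation.COFLIGHT.value], rng,
                cfg.affinity_gain, cfg.new_group_weight,
            )
            clusters = affinity_partition(
                attendees, affinity[Situation.DIURNAL_GROUND.value], rng,
                cfg.affinity_gain, cfg.new_group_weight,
            )
            # feeding clusters sit on a ring around the carcass, far enough
            # apart that only same-cluster pairs fall within 50 m
            n_cl = len(clusters)
            ring_km = max(0.8, 0.1 * n_cl / math.pi)
            angles = (np.arange(n_cl) + rng.uniform(-0.2, 0.2, n_cl)) * 2 * np.pi / n_cl
            cluster_pos = np.stack(
                [
                    carcass[0] + ring_km * 1000 * np.cos(angles) / m_lon,
                    carcass[1] + ring_km * 1000 * np.sin(angles) / m_lat,
                ],
                axis=1,
            )
            cluster_of = {i: c for c, grp in enumerate(clusters) for i in grp}

            # one rendezvous and arrival slot per co-flight group, staggered
            # so different groups are never near the carcass in flight together
            base_arrival = 14
            arrival_order = rng.permutation(len(cf_groups))
            for g, grp in enumerate(cf_groups):
                a_r = base_arrival + int(arrival_order[g])
                direction = 2 * np.pi * (g + rng.uniform(0.2, 0.8)) / len(cf_groups)
                r_km = rng.uniform(12.0, 25.0)
                rendezvous = np.array(
                    [
                        carcass[0] + r_km * 1000 * math.cos(direction) / m_lon,
                        carcass[1] + r_km * 1000 * math.sin(direction) / m_lat,
                    ]
                )
                leg_m = r_km * 1000.0
                n_common = max(2, _leg_n_slots(leg_m, cfg.flight_speed_range, interval_s, 5, rng))
                v_common = leg_m / (n_common * interval_s)
                a_g = a_r + n_common
                for i in grp:
                    off = rng.uniform(-1, 1, size=2)
                    off = off / max(np.linalg.norm(off), 1e-9) * rng.uniform(50, 400)
                    off_deg = np.array([off[0] / m_lon, off[1] / m_lat])
                    solo_m = _planar_dist_m(p0[i], rendezvous, lat0)
                    n_solo = _leg_n_slots(solo_m, cfg.flight_speed_range, interval_s, a_r - 2, rng)
                    v_solo = solo_m / (n_solo * interval_s)
                    dep = a_r - n_solo
                    # morning at the roost
                    lon[i, :dep], lat[i, :dep] = p0[i, 0], p0[i, 1]
                    speed[i, :dep] = ground_speed(dep)
                    # solo leg to the rendezvous
                    for k, t in enumerate(range(dep, a_r)):
                        frac = (k + 1) / n_solo
                        pos = p0[i] + (rendezvous - p0[i]) * frac + off_deg
                        lon[i, t], lat[i, t] = pos
                        speed[i, t] = np.clip(v_solo * rng.uniform(0.95, 1.05), *cfg.flight_speed_range)
                    # common leg toward the carcass, group-coherent
                    for k, t in enumerate(range(a_r, a_g)):
                        frac = k / n_common
                        pos = rendezvous + (carcass - rendezvous) * frac + off_deg
                        lon[i, t], lat[i, t] = pos
                        speed[i, t] = np.clip(v_common * rng.uniform(0.95, 1.05), *cfg.flight_speed_range)
                    arrive_feed[i] = a_g
                    day_pos[i] = cluster_pos[cluster_of[i]]
                if len(grp) > 1 and n_common >= 2:
                    for x in range(len(grp)):
                        for y in range(x + 1, len(grp)):
                            a, b = sorted((grp[x], grp[y]))
                            truth_rows.append(
                                (Situation.COFLIGHT.value, ids[a], ids[b], day, n_common)
                            )

        # non-attendees loiter at a solitary spot 1.5-2.8 km from the roost
        by_roost: dict[int, list[int]] = {}
        for i in loiterers:
            by_roost.setdefault(int(current_roost[i]), []).append(int(i))
        for r, members in by_roost.items():
            for slot_idx, i in enumerate(members):
                angle = 2 * np.pi * (slot_idx + rng.uniform(0.2, 0.8)) / len(members)
                dist_km = rng.uniform(1.5, 2.8)
                day_pos[i] = p0[i] + np.array(
                    [dist_km * 1000 * math.cos(angle) / m_lon, dist_km * 1000 * math.sin(angle) / m_lat]
                )
                dep = int(rng.integers(2, 6))
                lon[i, :dep], lat[i, :dep] = p0[i, 0], p0[i, 1]
                speed[i, :dep] = ground_speed(dep)
                # sub-threshold relocation hop (one slot)
                lon[i, dep], lat[i, dep] = day_pos[i]
                speed[i, dep] = min(dist_km * 1000 / interval_s, 4.9)
                arrive_feed[i] = dep + 1

        # nightly roosting: groups by nocturnal affinity, one roost per group
        night_groups = affinity_partition(
            np.arange(n), affinity[Situation.NOCTURNAL_GROUND.value], rng,
            cfg.affinity_gain, cfg.new_group_weight,
        )
        night_roost_of_group = _assign_groups_to_roosts(night_groups, preference, rng)
        night_roost = np.zeros(n, dtype=int)
        # globally staggered evening departures: distinct arrival offsets
        # (up to a cap) keep returning birds off each other's corridors
        ret_off = rng.permutation(max(n, 7)) % 13
        for g, grp in enumerate(night_groups):
            for i, off in zip(grp, ret_off[list(grp)]):
                night_roost[i] = night_roost_of_group[g]
                target = roost_point(night_roost[i])
                ret_m = _planar_dist_m(day_pos[i], target, lat0)
                if ret_m < 1.0:
                    arr = spd - 1 - int(off)
                    e_i = arr
                    n_ret = 0
                else:
                    n_ret = _leg_n_slots(ret_m, cfg.flight_speed_range, interval_s, spd, rng)
                    arr = spd - 1 - int(off)
                    e_i = arr - n_ret
                e_i = max(e_i, int(arrive_feed[i]))
                arr = e_i + n_ret
                v_ret = ret_m / max(n_ret, 1) / interval_s
                # daytime stationary period
                t0 = int(arrive_feed[i])
                for t in range(t0, e_i):
                    jit = rng.uniform(-15, 15, size=2)
                    lon[i, t] = day_pos[i, 0] + jit[0] / m_lon
                    lat[i, t] = day_pos[i, 1] + jit[1] / m_lat
                    speed[i, t] = ground_speed()
                # return leg
                for k, t in enumerate(range(e_i, min(arr, spd))):
                    frac = k / max(n_ret, 1)
                    pos = day_pos[i] + (target - day_pos[i]) * frac
                    lon[i, t], lat[i, t] = pos
                    speed[i, t] = np.clip(v_ret * rng.uniform(0.95, 1.05), *cfg.flight_speed_range)
                # overnight roost slots
                for t in range(min(arr, spd - 1), spd):
                    jit = rng.uniform(-1, 1, size=2) * min(roost_radius_m[night_roost[i]] * 0.3, 5.0)
                    lon[i, t] = target[0] + jit[0] / m_lon
                    lat[i, t] = target[1] + jit[1] / m_lat
                    speed[i, t] = ground_speed()
                depart_feed[i] = e_i

        # diurnal ground truth: overlap of same-cluster presence windows
        if attendees.size:
            for grp in clusters:
                for x in range(len(grp)):
                    for y in range(x + 1, len(grp)):
                        i, j = grp[x], grp[y]
                        start = int(max(arrive_feed[i], arrive_feed[j]))
                        end = int(min(depart_feed[i], depart_feed[j]))
                        if end - start >= 2:
                            a, b = sorted((i, j))
                            truth_rows.append(
                                (Situation.DIURNAL_GROUND.value, ids[a], ids[b], day, end - start)
                            )
        # nocturnal ground truth: realized roost co-occupancy
        for r in range(cfg.n_roosts):
            members = sorted(np.flatnonzero(night_roost == r))
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    truth_rows.append(
                        (
                            Situation.NOCTURNAL_GROUND.value,
                            ids[members[x]],
                            ids[members[y]],
                            day,
                            1,
                        )
                    )
        current_roost = night_roost

        epoch0 = day * cfg.epochs_per_day + cfg.day_start_offset
        filled = ~np.isnan(speed)
        rows, cols = np.nonzero(filled)
        all_lon.append(lon[rows, cols])
        all_lat.append(lat[rows, cols])
        all_speed.append(speed[rows, cols])
        all_epoch.append(epoch0 + cols)
        all_ind.append(np.array(ids)[rows])

    epochs = np.concatenate(all_epoch)
    base = pd.Timestamp(cfg.season_start)
    fixes = pd.DataFrame(
        {
            "individual_id": np.concatenate(all_ind),
            "timestamp": base + pd.to_timedelta(epochs * cfg.fix_interval_minutes, unit="m"),
            "lon": np.concatenate(all_lon),
            "lat": np.concatenate(all_lat),
            "ground_speed": np.concatenate(all_speed),
            "epoch": epochs,
        }
    ).sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    truth = GroundTruth(
        ids=ids,
        affinity=affinity,
        events=pd.DataFrame(
            truth_rows, columns=["situation", "id_a", "id_b", "day", "n_epochs"]
        ),
        home_roost=home,
    )
    return SimResult(fixes=fixes, roosts=roosts, feeding_sites=sites, truth=truth, config=cfg)


def degrade(
    fixes: pd.DataFrame, missing_fix_prob: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Drop each fix independently with the given probability."""
    if not 0.0 <= missing_fix_prob <= 1.0:
        raise ConfigurationError("missing_fix_prob must lie in [0, 1]")
    if missing_fix_prob == 0.0:
        return fixes.copy()
    keep = rng.random(len(fixes)) >= missing_fix_prob
    return fixes[keep].reset_index(drop=True)


def study_config_for(cfg: SimConfig) -> StudyConfig:
    """A StudyConfig matched to a simulated season: same grid and day
    window, season spanning the simulated days, tagging site at the
    region center.  The duration filter is relaxed below the study value
    only when the simulated season itself is shorter."""
    return StudyConfig(
        fix_interval_minutes=cfg.fix_interval_minutes,
        season_start=cfg.season_start,
        season_end=cfg.season_start + dt.timedelta(days=cfg.n_days),
        day_start=cfg.day_start,
        day_end=cfg.day_end,
        tagging_site=tuple(cfg.region_center),
        min_tracking_days=min(71, max(cfg.n_days - 1, 0)),
    )
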