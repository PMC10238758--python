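"""Interaction detection in the three situations, against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from helpers import (
    BASE_LAT,
    BASE_LON,
    brute_force_events,
    brute_force_joint_counts,
    event_tuples,
    fixes_from_rows,
    fixture_config,
    offset_lonlat,
    random_fixture,
    square_polygon,
)
from vulturenet.interactions import (
    Situation,
    UNASSIGNED,
    assign_roosts,
    classify_flight,
    detect_coflight_events,
    detect_diurnal_ground_events,
    joint_sampling_counts,
    nocturnal_cooccurrences,
    together_counts,
    verify_events,
)
from vulturenet.errors import ConsistencyError


# ---------------------------------------------------------------------------
# behaviour classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "speed,flying",
    [(6.0, True), (0.0, False), (5.0, False), (5.0001, True)],
)
def test_classify_flight_strict_threshold(speed, flying):
    assert classify_flight(speed, 5.0) is flying


def test_classify_flight_rejects_negative_speed():
    with pytest.raises(ValueError):
        classify_flight(-0.1, 5.0)


# ---------------------------------------------------------------------------
# co-flight detection
# ---------------------------------------------------------------------------


def test_coflight_two_slots_800m():
    cfg = fixture_config()
    df = fixes_from_rows(
        [
            ("a", 0, 0, 0, 10.0),
            ("a", 1, 500, 0, 10.0),
            ("b", 0, 800, 0, 12.0),
            ("b", 1, 1300, 0, 12.0),
        ]
    )
    events = detect_coflight_events(df, cfg)
    assert event_tuples(events) == [("a", "b", "coflight", 0, 1, 2)]


def test_coflight_single_slot_not_enough():
    cfg = fixture_config()
    df = fixes_from_rows([("a", 0, 0, 0, 10.0), ("b", 0, 900, 0, 12.0)])
    assert detect_coflight_events(df, cfg).empty


def test_coflight_requires_both_flying():
    cfg = fixture_config()
    df = fixes_from_rows(
        [("a", 0, 0, 0, 10.0), ("a", 1, 0, 0, 10.0), ("b", 0, 500, 0, 3.0), ("b", 1, 500, 0, 3.0)]
    )
    assert detect_coflight_events(df, cfg).empty


def test_coflight_missing_fix_breaks_run():
    cfg = fixture_config()
    rows = [("a", t, 0, 0, 10.0) for t in range(5)]
    rows += [("b", t, 400, 0, 10.0) for t in (0, 1, 3, 4)]  # slot 2 missing
    events = detect_coflight_events(fixes_from_rows(rows), cfg)
    assert event_tuples(events) == [
        ("a", "b", "coflight", 0, 1, 2),
        ("a", "b", "coflight", 3, 4, 2),
    ]


# ---------------------------------------------------------------------------
# diurnal ground detection
# ---------------------------------------------------------------------------


def test_diurnal_three_slots_20m():
    cfg = fixture_config()
    rows = [("a", t, 0, 0, 0.5) for t in range(3)] + [("b", t, 20, 0, 1.0) for t in range(3)]
    events = detect_diurnal_ground_events(fixes_from_rows(rows), {}, cfg)
    assert event_tuples(events) == [("a", "b", "diurnal", 0, 2, 3)]


def test_diurnal_inside_roost_excluded():
    cfg = fixture_config()
    roosts = {"R1": square_polygon(BASE_LON, BASE_LAT, half_m=60)}
    rows = [("a", t, 0, 0, 0.5) for t in range(2)] + [("b", t, 20, 0, 1.0) for t in range(2)]
    assert detect_diurnal_ground_events(fixes_from_rows(rows), roosts, cfg).empty
    # the same configuration away from the roost does qualify
    rows_far = [(i, t, dx + 5000, 0, s) for (i, t, dx, _dy, s) in rows]
    events = detect_diurnal_ground_events(fixes_from_rows(rows_far), roosts, cfg)
    assert len(events) == 1


def test_diurnal_60m_apart_no_event():
    cfg = fixture_config()
    rows = [("a", t, 0, 0, 0.5) for t in range(5)] + [("b", t, 60, 0, 1.0) for t in range(5)]
    assert detect_diurnal_ground_events(fixes_from_rows(rows), {}, cfg).empty


# ---------------------------------------------------------------------------
# detector equivalence with the brute-force oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(30))
def test_detectors_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    df = random_fixture(rng)
    cfg = fixture_config()
    roosts = {"R1": square_polygon(*offset_lonlat(30, 20), half_m=45)}
    got_cf = event_tuples(detect_coflight_events(df, cfg))
    exp_cf = brute_force_events(df, cfg, "coflight")
    assert got_cf == exp_cf
    got_dg = event_tuples(detect_diurnal_ground_events(df, roosts, cfg))
    exp_dg = brute_force_events(df, cfg, "diurnal", roosts=roosts)
    assert got_dg == exp_dg


def test_events_verify_against_raw_fixes(small_sim, small_sim_networks):
    """Post-hoc check: every detected event slot satisfies the distance,
    state and roost predicates when re-examined one fix at a time."""
    from vulturenet.simulate import study_config_for

    cfg = study_config_for(small_sim.config)
    res = small_sim_networks
    for label in ("coflight", "diurnal"):
        assert verify_events(res.events[label], res.fixes, cfg, roosts=small_sim.roosts)


# ---------------------------------------------------------------------------
# roost assignment
# ---------------------------------------------------------------------------


def _night_fixture(evening_dx, morning_dx, drop_evening=False, drop_morning=False):
    rows = []
    if not drop_evening:
        rows.append(("a", pd.Timestamp("2021-01-01 17:50"), *offset_lonlat(evening_dx, 0), 0.5))
    if not drop_morning:
        rows.append(("a", pd.Timestamp("2021-01-02 06:10"), *offset_lonlat(morning_dx, 0), 0.5))
    df = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lon", "lat", "ground_speed"])
    roosts = {"R": square_polygon(BASE_LON, BASE_LAT, half_m=30)}
    return df, roosts


@pytest.mark.parametrize(
    "evening_dx,morning_dx,drop_e,drop_m,roost,method",
    [
        (0, 9_000, False, False, "R", "LAST_FIX"),       # evening fix inside
        (9_000, 0, False, False, "R", "FIRST_FIX"),      # morning fix inside
        (-5_000, 5_000, False, False, "R", "MIDPOINT"),  # midpoint inside
        (9_000, 9_000, False, False, UNASSIGNED, "NONE"),
        (9_000, 0, False, True, UNASSIGNED, "NONE"),     # single far fix, no midpoint
    ],
)
def test_assign_roosts_branch_priority(evening_dx, morning_dx, drop_e, drop_m, roost, method):
    df, roosts = _night_fixture(evening_dx, morning_dx, drop_e, drop_m)
    cfg = fixture_config()
    out = assign_roosts(df, roosts, cfg)
    night = out[out["night_date"] == pd.Timestamp("2021-01-01").date()]
    assert len(night) == 1
    assert night.iloc[0]["roost_id"] == roost
    assert night.iloc[0]["method"] == method


def test_nocturnal_cooccurrence_rules():
    assignments = pd.DataFrame(
        [
            ("A", "2021-01-01", "R1", "LAST_FIX"),
            ("B", "2021-01-01", "R1", "FIRST_FIX"),
            ("C", "2021-01-01", "R2", "LAST_FIX"),
            ("D", "2021-01-01", UNASSIGNED, "NONE"),
            ("A", "2021-01-02", "R1", "LAST_FIX"),
        ],
        columns=["individual_id", "night_date", "roost_id", "method"],
    )
    events = nocturnal_cooccurrences(assignments)
    assert len(events) == 1
    row = events.iloc[0]
    assert (row.id_a, row.id_b, row.situation, row.start, row.n_epochs) == (
        "A", "B", "nocturnal", "2021-01-01", 1,
    )


# ---------------------------------------------------------------------------
# joint-sampling denominators and numerators
# ---------------------------------------------------------------------------


def test_joint_sampling_shared_slots():
    rows = [("a", t, 0, 0, 1.0) for t in range(10)] + [("b", t, 5000, 0, 1.0) for t in range(10)]
    counts = joint_sampling_counts(fixes_from_rows(rows), Situation.COFLIGHT)
    assert counts.at["a", "b"] == 10
    assert counts.at["a", "a"] == 0


def test_joint_sampling_disjoint_is_zero():
    rows = [("a", t, 0, 0, 1.0) for t in range(5)] + [("b", t + 5, 0, 0, 1.0) for t in range(5)]
    counts = joint_sampling_counts(fixes_from_rows(rows), Situation.DIURNAL_GROUND)
    assert counts.at["a", "b"] == 0


@pytest.mark.parametrize("seed", range(10))
def test_joint_sampling_matches_double_loop(seed):
    rng = np.random.default_rng(100 + seed)
    df = random_fixture(rng)
    counts = joint_sampling_counts(df, Situation.COFLIGHT)
    expected = brute_force_joint_counts(df)
    for (a, b), n in expected.items():
        assert counts.at[a, b] == n
        assert counts.at[b, a] == n
    np.testing.assert_array_equal(counts.values, counts.values.T)


def test_joint_sampling_nocturnal_counts_assigned_nights():
    assignments = pd.DataFrame(
        [
            ("A", "n1", "R1", "LAST_FIX"),
            ("B", "n1", "R2", "LAST_FIX"),
            ("A", "n2", "R1", "LAST_FIX"),
            ("B", "n2", UNASSIGNED, "NONE"),
        ],
        columns=["individual_id", "night_date", "roost_id", "method"],
    )
    counts = joint_sampling_counts(assignments, Situation.NOCTURNAL_GROUND, cohort=["A", "B"])
    assert counts.at["A", "B"] == 1  # only n1 has both actually assigned


def test_together_counts_slots_vs_events():
    events = pd.DataFrame(
        [
            ("a", "b", "coflight", 0, 2, 3),
            ("a", "b", "coflight", 7, 8, 2),
        ],
        columns=["id_a", "id_b", "situation", "start", "end", "n_epochs"],
    )
    cohort = ["a", "b", "c"]
    slots = together_counts(events, cohort, numerator="slots")
    assert slots.at["a", "b"] == 5
    bouts = together_counts(events, cohort, numerator="events")
    assert bouts.at["a", "b"] == 2
    assert slots.at["a", "c"] == 0


def test_together_counts_rejects_pair_outside_cohort():
    events = pd.DataFrame(
        [("a", "x", "coflight", 0, 1, 2)],
        columns=["id_a", "id_b", "situation", "start", "end", "n_epochs"],
    )
    with pytest.raises(ConsistencyError):
        together_counts(events, ["a", "b"])


def test_detection_is_symmetric_and_deterministic():
    cfg = fixture_config()
    rng = np.random.default_rng(77)
    df = random_fixture(rng)
    e1 = detect_coflight_events(df, cfg)
    e2 = detect_coflight_events(df.sample(frac=1.0, random_state=3).reset_index(drop=True), cfg)
    assert event_tuples(e1) == event_tuples(e2)
    assert (e1["id_a"] < e1["id_b"]).all()
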