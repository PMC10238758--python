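"""Generate a synthetic tracking season and look at what the tags record.

A small population (10 birds, 20 days) is simulated with planted social
structure: each day the birds leave their roost, fly to a carcass in
co-flight groups, feed in tight ground clusters, and return to a
communal roost for the night.  The printed numbers are the raw material
of the whole analysis: fix counts on the 10-min daytime grid and the
true co-occurrence bouts the generator planted.
"""

import numpy as np

from vulturenet import SimConfig, simulate

cfg = SimConfig(n_individuals=10, n_days=20, rng_seed=42)
res = simulate(cfg)

print(f"individuals : {cfg.n_individuals}, days: {cfg.n_days}")
print(f"fixes       : {len(res.fixes)} "
      f"({cfg.slots_per_day} per bird-day, complete sampling)")
print(f"roosts      : {len(res.roosts)}, feeding sites: {len(res.feeding_sites)}")

speeds = res.fixes["ground_speed"]
print(f"fix speeds  : {np.mean(speeds > 5):.0%} flying (>5 m/s), "
      f"{np.mean(speeds <= 5):.0%} on the ground")

truth = res.truth.events
print("\nplanted co-occurrence bouts (ground truth):")
for sit, grp in truth.groupby("situation"):
    print(f"  {sit:10s}: {len(grp):5d} bouts over "
          f"{grp[['id_a', 'id_b']].drop_duplicates().shape[0]} pairs")
print("\nThese bouts are what the detectors in example 02 must recover "
      "from positions and speeds alone.")
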