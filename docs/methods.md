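# Methods

This note documents the models, rules and numerical choices implemented in
`vulturenet`, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Data model and epoch alignment

A fix is (individual, timestamp, lon/lat in WGS84 decimal degrees, ground
speed in m/s). Tags record only during daytime on a nominal 10-min schedule,
but devices are not synchronized across individuals. We discretize time into
fixed wall-clock slots anchored at the season start
(`epoch = floor((t − season_start)/interval)`); when an individual has two
fixes in one slot, the fix nearest the slot midpoint is kept. Two birds are
*simultaneously sampled* in a slot iff both have a fix in it. This is
deterministic and transitive, at the cost of occasionally separating fixes
9–11 min apart that straddle a slot boundary; a test compares slot pairing
against raw |Δt| ≤ interval pairing and confirms slot pairing is strictly
conservative.

Timestamps are treated as naive local study time. The day window defaults to
a fixed 06:00–18:00 local clock rather than a computed civil-daylight window:
the tags only record in daytime, so the boundary's sole job is to decide
which fix is "last of the evening" / "first of the morning", and a fixed
window is deterministic and matches the simulator's emission grid. Both
boundaries are configurable.

## Cohort filters

An individual is retained iff (a) it has strictly more than
`min_tracking_days` (default 71) distinct calendar days with at least one fix
inside the season window, and (b) none of its season fixes lies farther than
`max_range_km` (default 400) from its tagging site — a single excursion
disqualifies. The tagging site may be shared or per-individual. Exclusions
are reported with reasons.

## Interaction inference

Behavioural state is classified from the reported ground speed with a strict
threshold: flying iff speed > 5 m/s (equality is ground, since the source
definitions use "faster than"/"slower than").

* **Co-flight**: for each unordered pair, maximal runs of consecutive slots
  in which both are flying and the haversine distance is ≤ 1000 m; runs of
  ≥ 2 slots become events. A slot where either bird lacks a fix breaks the
  run — "consecutive fixes" is taken literally, with no gap bridging.
* **Diurnal ground**: same run logic with both on the ground and distance
  ≤ 50 m; any slot where either fix lies inside a roost polygon is
  disqualified and breaks runs (daytime presence at a roost is not feeding).
* **Nocturnal ground**: each night, a bird is assigned to a roost polygon by
  the first of: last evening fix inside a polygon; first next-morning fix
  inside a polygon; the geographic midpoint of those two fixes inside a
  polygon ("average of the two positions" is operationalized as the
  midpoint — a distance cannot lie in a polygon); otherwise unassigned.
  Every pair assigned to the same roost on a night co-occurs once.

Distances use the haversine formula on a sphere of radius 6,371,000 m;
polygon containment is planar in lon/lat with boundary points counting as
inside. Roost polygons are ~10²–10³ m², where the planar approximation is
exact to far below GPS error, and the 50/1000 m thresholds are far above
haversine error at study scale.

## Networks

Edge weight is the simple ratio index, `together / joint_sampled`, where the
sampling unit is the epoch slot for diurnal situations (a 3-slot bout
contributes 3 to the numerator; event-level counting is available as
`sri_numerator="events"`) and the night for the nocturnal situation
(denominator = nights in which both birds have an actual roost assignment).
Keeping numerator and denominator in the same unit guarantees SRI ∈ (0, 1]
for emitted edges. Pairs never jointly sampled get **no edge**, not weight 0:
an unobservable dyad is not an observed non-association. Nodes are the full
filtered cohort, isolates included. The aggregate network sums the three
layer weights per pair.

Centralities per network: degree (count of unique partners), strength (sum
of incident SRI weights), and weighted PageRank computed by dense power
iteration with damping 0.85 (the conventional default; the source analysis
delegates to a standard implementation without stating it), tolerance 1e-12,
cap 10,000 iterations. Transition probabilities are proportional to edge
weights; isolates (zero strength) teleport uniformly so scores always form a
proper distribution. Scores are snapped to 12 decimals after convergence so
exactly-symmetric nodes receive exactly equal scores — otherwise sub-
tolerance iteration noise would manufacture meaningless rank differences in
degenerate graphs. Tests cross-check against networkx's independent
implementation to 1e-9. Whether the original analysis used edge weights in
PageRank is not stated; weighted is the default here and the unweighted
variant is a one-line configuration away (binary weight matrix).

## Permutation reference model

For each of the nine (measure × situation) cells we report the Spearman
correlation (mean ranks on ties; undefined and flagged when either vector is
constant) between layer and aggregate centralities, and a null built by, per
iteration: independently permuting node identities within each layer,
rebuilding the aggregate from the permuted layers, recomputing all
centralities, and recording ρ per cell. Defaults: 10,000 iterations, all
randomness from one seed with per-iteration substreams spawned
deterministically (results do not depend on execution order).

Two consequences of this design are worth stating explicitly:

* Because each permuted layer still contributes to the permuted aggregate, a
  layer that dominates the aggregate is strongly correlated with it under
  the null too. Significance therefore measures **cross-layer alignment of
  social positions** — whether a bird's position in this situation lines up
  with its positions in the others — not the layer's raw share of the
  aggregate. A dominant layer with structure independent of the others is
  correctly non-significant.
* Iterations in which a centrality vector is constant have undefined ρ;
  they are excluded from the null and counted (`n_excluded`). Whether to
  instead assign ρ = 0 is a judgment call; exclusion avoids inventing a
  correlation value for an undefined statistic.

The primary p-value is the doubled one-sided count-based permutation p with
the +1 correction, capped at 1 — conservative, reproducible, and never
exactly zero. The cruder "observed outside the central 95% of the null"
criterion is reported alongside as a boolean for comparability with the
quantile phrasing common in this literature. Calibration under a true null
(independently shuffled centrality vectors) is part of the acceptance
checks: the rejection rate at α = 0.05 with 999 iterations sits near the
analytic value 2·24/1000 = 0.048.

## The synthetic-data generator

`simulate.SimConfig` defaults emulate the study conditions: 29 individuals,
120-day season, 10-min fixes in a 06:00–18:00 window, 6 communal roost
polygons with lognormal areas around 800 m², 8 feeding sites in a
~200 × 200 km region, flight speeds 8–20 m/s, ground speeds 0–2 m/s,
optional independent fix loss.

Daily schedule: birds start inside their previous night's roost polygon,
join co-flight groups that rendezvous and commute to the day's carcass site
(group members within 400 m lateral offsets; distinct per-group arrival
slots keep different groups off each other's corridors), feed in ground
clusters on a ring around the carcass (within-cluster spread ≤ 30 m,
clusters ≥ ~200 m apart so only same-cluster pairs fall within 50 m), and
return on staggered corridors to a roost chosen by that night's grouping,
always ending the day inside the polygon. Non-attending birds loiter alone
a few km from their roost. Movement between waypoints is linear
interpolation at fix epochs: the pipeline consumes only per-slot positions
and speed classes, so continuous-time kinematic realism would add nothing
the detectors can see.

Social structure is planted as one symmetric pairwise affinity matrix per
situation. Defaults are generated from 2-D latent social spaces
(affinity = exp(−distance/0.15)); each situation's space is a normalized
blend of a shared population space and a situation-specific space
(`social_alignment`, default 0.7), because in real multilayer systems social
positions carry over partially — and that partial alignment is precisely
what the permutation test detects. Groups (flight groups, feeding clusters,
nightly roost groups) form by a sequential affinity-weighted aggregation:
each bird joins an existing group with weight `3 × Σ affinity to members` or
opens a new group with weight `1 × Π(1 − affinity to placed birds)`, so zero
affinity yields solitary birds and affinity 1 forces a pairing. Groups draw
roosts from member preferences without replacement while roosts remain, so
co-roosting reflects the planted nocturnal structure rather than collisions.
The pre-season night (visible to the pipeline through the first morning's
fixes) is generated by the same mechanism and logged in the ground truth as
night −1.

Chosen regime and its consequence: the grouping constants were set so that
planted affinity is a strong monotone predictor of the estimated SRI
(recovery Spearman ≈ 0.9 per situation), which requires interaction rates
high enough that sampling noise does not scramble pair ranks. At those
rates, over 120 days nearly every pair co-occurs at least once per
situation, so the simulated networks are near-complete and **degree is
near-constant** — degree-cell correlations on synthetic defaults are weak or
degenerate (reported as such), and the strength/PageRank cells carry the
planted signal. Sparser regimes (smaller latent scale, higher solo weight)
produce realistic degree variation but degrade affinity recovery to ρ
≈ 0.5–0.8; users who want degree-informative synthetic data should lower
`affinity_tau`/`affinity_gain` and accept noisier recovery. Field data is
not expected to be near-complete; this is a property of the chosen
synthetic regime, not of the method.

What the generator does **not** emulate: thermal soaring and altitude
structure, interactions with untagged conspecifics, GPS position error,
tag-specific fix-loss patterns (loss is i.i.d.), demographic turnover, and
carcass depletion dynamics. Passing tests therefore demonstrate that the
inference machinery is correct and well-calibrated on data whose generating
process matches the stated detection rules — not that those rules are the
right operationalization for any particular field system.

## Problem sizes in the test and acceptance runs

Unit and property tests run on small fixtures (≤ 6 individuals, ≤ 50 slots)
with exact brute-force oracles, and on short simulated seasons (10–15
birds, 12–20 days). The acceptance script runs the full default study scale
(29 birds, 120 days, 10,000 permutations), 10 simulated seasons for
affinity recovery, and 500 null datasets × 999 iterations for p-value
calibration; one run takes under a minute on a single CPU.

## Known limitations

* The 400-km range filter and tagging-site reference support shared or
  per-individual sites, but the choice materially affects which birds
  survive filtering when capture sites differ.
* Roost assignment trusts the polygon set: co-roosting at an unmapped site
  is invisible (unassigned nights shrink the nocturnal denominator rather
  than biasing weights, but reduce power).
* The midpoint fallback for roost assignment is a geometric reading of an
  ambiguous prescription; both it and the slot-vs-event SRI numerator are
  configurable because the original choices are not recoverable from the
  source text.
* Spearman cells with constant centrality vectors are undefined; the report
  flags them rather than guessing.
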