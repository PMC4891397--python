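# Methods

This note documents the models implemented in `roomwalk`, the
parameter defaults and why they have the values they do, the numerical
and design choices that were genuinely open, and what the synthetic
data can and cannot establish.

## The environment model

A building is an undirected, connected graph.  Nodes are rooms,
corridors and staircase landings, each with a floor index (0 =
ground), planar coordinates in metres, an optional block label and
optional behavioural annotations; edges are doors, corridor links or
staircases.  Staircase edges are the only edges allowed to join
(adjacent) floors.  The 3-D position of a room is
`(x, y, floor · floor_height)` with `floor_height = 4.0 m` by default;
this vertical spacing matters only for the radius of gyration, and any
positive constant preserves the ordering-based results.

Rooms, not doorways, are the graph's nodes; multiple doors between the
same pair of rooms would collapse to a single edge.  A *hop* is one
transition between adjacent rooms, so a trajectory of n room visits has
n − 1 hops.  Simulated trajectories are timestamped at a nominal 6
seconds per hop — a scale constant chosen so that a ~250-hop
exploration lasts ~25 minutes; no computation depends on it.

Two behavioural annotations stand in for geometry, which is not
modelled: `corner` marks a degree-2 corridor as a corner rather than a
straight segment, and `door_visibility` records whether the far door of
a two-door room is visible from the entry door.  They exist because
walkers behave differently at these location types, not because the
graph could distinguish them topologically.

### The `palace44` fixture

The packaged 44-room, three-floor palace satisfies every structural
fact the analyses depend on: 44 rooms over 3 floors; four staircases
from the ground floor to the middle floor (two rising into Block A, one
into Block B, one into Block C); exactly one staircase serving the top
floor; a dead-end *dorm corridor* carrying rooms D1 and D2, attached to
the *Block A main corridor* at one end only; and Block B reachable
on-floor only through the rooms DB2 (hidden far door) and The Lounge
(visible far door).  The remaining adjacency, the room names beyond the
documented ones, and the coordinates are a frozen, arbitrary-but-fixed
approximation: all quantitative checks in this package depend only on
the documented facts, not on the undocumented details.  The default
start room is the ground-floor entrance (`G_ENT`).

## Agent families

All walkers draw from a single `numpy` generator per run; one uniform
draw resolves one choice, and weighted choices with equal weights
consume the stream exactly like unweighted ones.  This makes degenerate
parameterisations reduce to simpler agents *seed for seed*, which the
tests exploit.

**Unbiased random walker.**  Uniform choice among neighbours.  Its
visit shares converge to the degree law `π(r) = deg(r) / 2|E|`, which
serves as a closed-form oracle.

**Perfect m-step memory agent.**  The memory window holds the last m
*occupied* rooms, current room included (so m = 1 remembers only the
room it stands in and degenerates to the random walker, as does
m = 0).  Each hop:

1. if some neighbour is outside the window, choose uniformly among
   those;
2. otherwise scan the window from most recent to oldest for the nearest
   *unexplored junction* — a remembered room with a neighbour outside
   the window — and retrace the remembered path to it one hop per step;
3. if no junction is remembered, choose uniformly among all
   neighbours.

The window updates on every hop, including backtrack hops, after the
step is taken.  Backtrack hops count as hops: efficiency comparisons
would otherwise favour agents that teleport.

*Backtrack design.*  The route to the junction is fixed when the
backtrack is decided (re-deriving it each hop can stall at large m,
because backtrack hops displace window entries and distant junctions
fall out of memory mid-route).  The unexplored direction, however, is
**not** chosen in advance: on arrival the junction's out-of-window
neighbours are unexplored options and rule 1 draws among them.  An
earlier variant froze the direction at decision time; that gives the
walker a decision variable that outlives its window — effectively a
memory deeper than m — and measurably shifted the Markov order at which
exploration efficiency saturates.  Since the agent's defining property
is *having only an m-step memory*, no decision variable is allowed to
outlive the window.

**m-th-order Markov agent.**  Contexts are exact room-id tuples; with
44 rooms there is no defensible room-category abstraction that would
shrink the state space, so none is used.  Estimation counts every
contiguous length-(m+1) window in the (phase-filtered) corpus; windows
never span trajectory boundaries or phase changes.  Estimation defaults
to exploration-phase steps, the phase in which unguided search happens.
A query backs off: order m → m−1 → … → 1 → uniform over the current
room's neighbours.  Single-level fallback would deadlock — a simulated
agent can reach contexts absent at every order — so the recursion is
total by construction.  Lower-order tables are derived lazily from the
same corpus, keeping the whole back-off chain on one provenance.
Support is automatically restricted to graph neighbours because corpus
trajectories are adjacency-validated.

No statistical order-selection criterion (AIC/BIC and relatives) is
offered: with a 44-state chain and ~10⁴ windows these criteria are
unreliable, and the package's approach is to probe order by simulation
instead (the ensemble sweeps).

## Termination and ensembles

Walks stop at full coverage, at a target coverage, or after a fixed
hop count, always under a safety cap (default 100 000 hops); a capped
walk is returned flagged `truncated`.  Replicates are seeded by a
counter-based spawn `SeedSequence((master_seed, index))`, so ensembles
are reproducible and order-independent.

Ensembles either run a fixed replicate count or batch until the running
variance of the radius of gyration stabilizes: batches of 500,
relative variance change below 1 % for 3 consecutive batches, capped at
30 000 replicates.  The rule is standard; the four numbers are this
package's declared defaults (configurable and logged), chosen to be
conservative at the scale of the packaged environment.

In hops-to-coverage summaries, replicates that fail to reach the target
before the cap are excluded and counted, never imputed at the cap —
imputation would bias means invisibly, exclusion is visible in the
output.

The radius of gyration is computed over the time-ordered step sequence
(revisits weighted by occupancy) in 3-D.  A 2-D variant
(`use_3d=False`) is provided; the stabilization rule behaves the same
under either, since the vertical term is bounded by the floor spacing.

## Visit statistics

Normalized visits `α_x(r) = f_x(r) / Σ_a f_x(a)` and visit ratios
`y_p(r) = α_p(r) / α_rw(r)` remove the effect of node degree from room
popularity.  The random-walker baseline `α_rw` is an *ensemble*
average: visits pooled over seeded walks.  A single 10⁵-hop walk is not
enough on `palace44` — the top floor hangs off one staircase, so floor
occupancy decorrelates slowly and per-room shares still fluctuate by
~10 % at that length; the packaged checks pool ~4·10⁶ hops, where the
maximum per-room deviation from the degree law is measured at 1–4 %.

The floor-normalized ratio recomputes both α's with denominators
restricted to same-floor rooms before taking the ratio.  Between-floor
visit-mass differences then cancel exactly, so differences between the
plain and floor-normalized maps isolate staircase/floor preference —
the floor-first signature — from within-floor structure.

Ratio maps are exported with highlight sets at 1.05 / 0.95 (a ±5 %
parity band, configurable).

**Decision points** are nodes of degree ≥ 2, classified as: staircase
landings; branching (degree ≥ 3); simple corridors vs corners
(degree-2 corridors, split by annotation, defaulting to corridor);
two-door rooms with visible vs hidden far doors (split by annotation,
defaulting to visible with a warning).  Degree-1 rooms are excluded —
the only move is back out, so no decision is measurable.  Reversal
rates are reported per traversal (entering and leaving a classified
node), with counts and denominators; per-player aggregation can be
built from the per-trajectory counts if needed.

**Dead-end branch profiles** tabulate, for the k-th arrival of each
walker at a junction, the fraction turning into the branch, and among
entries the fraction back at the junction within a window of hops
(default twice the branch diameter; window 1 means "headed right
back").  An option restricts to arrivals after the whole branch had
been visited — the regime where re-entry serves no exploratory purpose,
so immediate exit signals that the branch is remembered.

## The synthetic-player generator

The generator exists because the kind of data this analysis needs —
complete movement logs of a ~44-player cohort exploring a multi-floor
building to ~89 % coverage — is not publicly available.  It emulates
that cohort with a walker built on the m-step memory agent plus four
interpretable imperfections, applied per hop in this order:

1. **forgetting** — each window entry is independently dropped with
   probability `p_forget`.  Holes punched in the window mean the
   remembered path can skip rooms; a backtrack bridges such a gap with
   a graph shortest path.  Independent per-entry dropout (rather than
   deterministically shortening the window) keeps one parameter and
   produces graded, human-like recall errors;
2. **reversal** — with a class-dependent probability the walker goes
   back through the door it entered by.  Defaults:
   straight corridor 0.05, staircase 0.05, corner 0.08, two-door room
   with visible far door 0.20, with hidden far door 0.40;
3. **pruning** — having just stepped from a junction into a dead-end
   branch whose rooms it has all seen before, the walker heads straight
   back with probability `p_prune = 0.80`.  This is deliberately keyed
   to the *ever-visited* set, not the window: it models a long-term
   memory signature.  The walk's start room is never treated as a
   prunable pocket — the entrance is where exploration began, not a
   dead end discovered along the way;
4. **floor-averse memory choice** — the memory agent's rule 1, with
   staircase options down-weighted by `floor_aversion` whenever an
   unexplored same-floor option remains (the floor-first strategy).

Walks terminate at a target coverage, 89 % by default, abstracting a
checkpoint design that forces most of the building to be seen.  On the
44-room palace, 89 % works out to 40 rooms (90.9 %).

With all four mechanisms disabled the generator is seed-for-seed
identical to the perfect memory agent, and at `m_mem = 0` to the random
walker — the degeneracy chain the tests assert.

**Defaults and calibration.**  `n_players = 44`, `m_mem = 7`,
reversal and prune probabilities as above.  The two free noise
parameters were calibrated once against the emulated cohort's two
printed conditions — termination at 89 % coverage after a mean of
roughly 253 hops — giving `p_forget = 0.18` and `floor_aversion = 0.5`
(measured cohort means ≈ 250 hops across seeds), and then frozen.
Higher-entropy alternatives (e.g. `p_forget = 0.25`) overshoot the hop
condition at any floor-aversion value and were rejected on that ground
alone.

**Parameter recovery.**  Recovering the reversal and prune settings
from generated logs needs an experimental design that separates the
*decision* probabilities from returns forced by the memory rule: with a
7-room window the far door of a two-door room is often inside the
window, and the walker turns back for memory reasons ~10 % of the time,
biasing the measured rate upward.  The recovery cohort therefore uses
`m_mem = 2, p_forget = 0, floor_aversion = 1`: a 2-step window makes
the natural reversal probability at every degree-2 decision point
exactly zero, so measured rates estimate the generator's probabilities
directly (measured: 0.401 ± binomial noise against a setting of 0.40
pooled over 12 cohorts).  Prune is recovered as the immediate-exit
fraction (window 1) among branch entries made after the branch was
fully visited.

**What passing tests do and do not show.**  The generator reproduces
the *recoverable structure* the pipeline is meant to detect: a known
memory depth, known reversal and prune probabilities, a floor-first
bias, and the cohort-scale hop/coverage statistics.  It does not claim
behavioural fidelity beyond that: real players have long-term spatial
memory, landmark recognition, goal-directed phases and heterogeneous
strategies, none of which are modelled.  Results on synthetic cohorts
validate the *machinery* (estimation, sweeps, metrics), not conclusions
about human cognition.

## Memory-depth recovery: what to expect

The headline end-to-end check generates a default 44-player cohort
(`m_mem = 7`), estimates Markov agents of orders 1–10 from it, and
sweeps hops-to-50 %-coverage at 1 000 replicates per order.  The curve
improves sharply up to the cohort's memory depth (order 2 → 7 gain
≈ 10 hops, many standard errors) and flattens after (order 8 → 10 gap
≈ 0).  Two caveats are inherent and documented rather than hidden:

* the plateau comparison is made at 2 standard errors of the replicate
  noise, but with only 44 training trajectories the order-8 and
  order-10 tables are genuinely different policies (context sparsity),
  which adds a corpus-level scatter of ~0.8 hops to the gap; on an
  unlucky cohort seed the 2-SE check can fail without anything being
  wrong;
* order-10 contexts from 44 trajectories are mostly singletons, so very
  high orders drift toward replaying individual synthetic players — an
  estimation artefact that caps how clean any plateau can be at this
  corpus size.

## Numerical choices and degenerate inputs

* Distributions returned by the Markov query sum to 1 within 1e-12;
  normalized visit profiles within 1e-9.
* Neighbour lists are sorted once per environment; all iteration orders
  are deterministic, so identical seeds give byte-identical outputs.
* Uniform choice is `options[int(u · len(options))]`; weighted choice
  walks the cumulative distribution on the same single draw.
* Self-loops (consecutive identical rooms) are rejected at log-read
  time: the room graph has no self-edges, and repeated rows are
  upstream sensor noise.
* A single-room trajectory has coverage `100/|V|` %, an empty movement
  graph is rejected, a zero-hop run returns the start room only, and an
  isolated node raises immediately.
* `dataset_size_sensitivity` reports the subsample seed next to every
  row; fraction 1.0 reproduces the full-corpus result exactly under the
  same master seed.

## Known limitations

* The palace adjacency beyond the documented structural facts is an
  approximation; absolute hop counts on it are fixture-specific, and
  only ordering/recovery properties should be compared across
  environments.
* Phase labels are carried end to end, but the generator emits
  exploration-phase trajectories only; knowledge-testing behaviour is
  not modelled.
* No within-room positions, view directions or pointer trajectories;
  visibility is a per-node annotation, not a ray-cast.
* Radius of gyration defaults to 3-D positions with the declared floor
  spacing; published mobility statistics sometimes use 2-D projections,
  so the switch is exposed.
* Single-machine batching only; ensembles are seeded for
  embarrassing parallelism but no distributed executor is provided.
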