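"""Descriptive statistics of exploration behaviour.

Covers the normalized room-visit share alpha(r) = f(r) / sum_a f(a), the
visit ratio y(r) = alpha_player(r) / alpha_random_walker(r) that removes
the effect of node degree (a random walker on an undirected graph visits
room r in proportion to degree(r) / 2|E| at stationarity), a
floor-normalized variant that separates between-floor from within-floor
preferences, the radius of gyration of a walk, the classification of
rooms into decision-point types, per-type direction-reversal rates, and
the revisit/immediate-exit profile of a dead-end branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .agents import TerminationRule, run_agent
from .environment import EnvironmentGraph
from .trajectories import MovementGraph, Trajectory, TrajectoryCorpus

# decision-point classes
SIMPLE_CORRIDOR = "simple_corridor"
STAIRCASE = "staircase"
SIMPLE_CORNER = "simple_corner"
ROOM_TWO_DOOR_VISIBLE = "room_two_door_visible"
ROOM_TWO_DOOR_HIDDEN = "room_two_door_hidden"
BRANCHING = "branching"
DECISION_CLASSES = (
    SIMPLE_CORRIDOR,
    STAIRCASE,
    SIMPLE_CORNER,
    ROOM_TWO_DOOR_VISIBLE,
    ROOM_TWO_DOOR_HIDDEN,
    BRANCHING,
)

#: default highlight band for visit-ratio maps (5 % above/below parity)
RATIO_HIGH = 1.05
RATIO_LOW = 0.95


@dataclass
class VisitProfile:
    """Normalized visit shares alpha(r), summing to 1."""

    shares: dict[str, float]
    source: str = "player"

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if self.shares and abs(total - 1.0) > 1e-9:
            raise ValueError(f"visit shares sum to {total}, not 1")

    def __getitem__(self, room: str) -> float:
        return self.shares.get(room, 0.0)


def normalized_visits(
    mg: MovementGraph | Mapping[str, int], source: str = "player"
) -> VisitProfile:
    """alpha(r) = f(r) / total visits, from a movement graph or raw counts."""
    counts = mg.visit_counts if isinstance(mg, MovementGraph) else dict(mg)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no visits recorded")
    return VisitProfile({r: c / total for r, c in counts.items()}, source=source)


def pooled_profile(
    trajectories: Iterable[Trajectory], source: str = "pooled"
) -> VisitProfile:
    """Visit shares pooled over an ensemble of trajectories."""
    counts: dict[str, int] = {}
    for t in trajectories:
        for room in t.rooms:
            counts[room] = counts.get(room, 0) + 1
    return normalized_visits(counts, source=source)


def random_walk_baseline(
    env: EnvironmentGraph,
    hops: int = 100_000,
    n_walks: int = 10,
    seed: int = 0,
    start: str | None = None,
) -> VisitProfile:
    """Empirical visit shares of the average unbiased random walker,
    pooled over ``n_walks`` seeded walks of ``hops`` hops each."""
    rule = TerminationRule("fixed_hops", hops, cap=hops)
    walks = [
        run_agent("random", env, rule, np.random.SeedSequence((seed, i)), start=start)
        for i in range(n_walks)
    ]
    return pooled_profile(walks, source="rw")


def degree_stationary_profile(env: EnvironmentGraph) -> VisitProfile:
    """Closed-form stationary shares of the random walk: degree/(2|E|)."""
    two_e = 2 * env.graph.number_of_edges()
    return VisitProfile(
        {r: env.degree(r) / two_e for r in env.room_ids()}, source="stationary"
    )


@dataclass
class RatioResult:
    """Visit ratios y(r); rooms with zero baseline share are flagged,
    not scored."""

    values: dict[str, float]
    flagged: tuple[str, ...] = ()

    def __getitem__(self, room: str) -> float:
        return self.values[room]

    def highlights(
        self, high: float = RATIO_HIGH, low: float = RATIO_LOW
    ) -> dict[str, tuple[str, ...]]:
        return {
            "over": tuple(sorted(r for r, y in self.values.items() if y > high)),
            "under": tuple(sorted(r for r, y in self.values.items() if y < low)),
        }


def visit_ratio(player: VisitProfile, baseline: VisitProfile) -> RatioResult:
    """y(r) = alpha_player(r) / alpha_baseline(r)."""
    values, flagged = {}, []
    for room, a in player.shares.items():
        b = baseline[room]
        if b > 0:
            values[room] = a / b
        else:
            flagged.append(room)
    return RatioResult(values, tuple(sorted(flagged)))


def floor_normalized_visit_ratio(
    player: VisitProfile, baseline: VisitProfile, env: EnvironmentGraph
) -> RatioResult:
    """Visit ratio with shares renormalized within each floor, removing
    between-floor visit-mass differences (floor-first detection)."""

    def per_floor(profile: VisitProfile) -> dict[str, float]:
        floor_tot: dict[int, float] = {}
        for room, a in profile.shares.items():
            floor_tot[env.floor_of(room)] = floor_tot.get(env.floor_of(room), 0.0) + a
        return {
            room: (a / floor_tot[env.floor_of(room)]) if floor_tot[env.floor_of(room)] > 0 else 0.0
            for room, a in profile.shares.items()
        }

    p_floor = per_floor(player)
    b_floor = per_floor(baseline)
    values, flagged = {}, []
    for room, a in p_floor.items():
        b = b_floor.get(room, 0.0)
        if b > 0:
            values[room] = a / b
        else:
            flagged.append(room)
    return RatioResult(values, tuple(sorted(flagged)))


# -- decision points -----------------------------------------------------


def classify_rooms(env: EnvironmentGraph) -> dict[str, str]:
    """Classify every potential decision point (degree >= 2 node).

    Degree-1 rooms are excluded: the only move there is back out, so no
    decision is measurable.  Two-door rooms lacking a door-visibility
    annotation default to the visible class with a warning.
    """
    classes: dict[str, str] = {}
    for rid in env.room_ids():
        room = env.rooms[rid]
        deg = env.degree(rid)
        if deg < 2:
            continue
        if room.category == "staircase_landing":
            classes[rid] = STAIRCASE
        elif deg >= 3:
            classes[rid] = BRANCHING
        elif room.category == "corridor":
            classes[rid] = SIMPLE_CORNER if room.corner else SIMPLE_CORRIDOR
        else:  # two-door room
            if not room.door_visibility:
                warnings.warn(
                    f"two-door room {rid!r} has no door_visibility annotation; "
                    "classified visible",
                    stacklevel=2,
                )
                classes[rid] = ROOM_TWO_DOOR_VISIBLE
            elif "hidden" in room.door_visibility.values():
                classes[rid] = ROOM_TWO_DOOR_HIDDEN
            else:
                classes[rid] = ROOM_TWO_DOOR_VISIBLE
    return classes


@dataclass
class ReversalStat:
    reversals: int
    traversals: int

    @property
    def rate(self) -> float:
        return self.reversals / self.traversals


def reversal_rates(
    corpus: TrajectoryCorpus,
    env: EnvironmentGraph,
    phase_filter: str | None = None,
) -> dict[str, ReversalStat]:
    """Fraction of traversals through each decision-point class that
    exit via the entry edge (the walker turns back)."""
    classes = classify_rooms(env)
    stats: dict[str, ReversalStat] = {}
    for traj in corpus:
        for i in range(1, traj.n_steps - 1):
            if phase_filter is not None and traj.phases[i] != phase_filter:
                continue
            cls = classes.get(traj.rooms[i])
            if cls is None:
                continue
            st = stats.setdefault(cls, ReversalStat(0, 0))
            st.traversals += 1
            if traj.rooms[i + 1] == traj.rooms[i - 1]:
                st.reversals += 1
    return stats


# -- radius of gyration --------------------------------------------------


def radius_of_gyration(
    trajectory: Trajectory, env: EnvironmentGraph, use_3d: bool = True
) -> float:
    """Root-mean-square distance of the time-ordered step positions from
    their centroid; revisited rooms are weighted by occupancy.  With
    ``use_3d`` the vertical coordinate is floor * floor_height."""
    pos = np.array([env.position3d(r) for r in trajectory.rooms], dtype=float)
    if not use_3d:
        pos = pos[:, :2]
    centroid = pos.mean(axis=0)
    return float(np.sqrt(((pos - centroid) ** 2).sum(axis=1).mean()))


# -- dead-end branch revisits -------------------------------------------


def branch_revisit_profile(
    corpus: TrajectoryCorpus,
    junction: str,
    branch_rooms: Iterable[str],
    env: EnvironmentGraph,
    phase_filter: str | None = None,
    exit_window: int | None = None,
    require_prior_full_visit: bool = False,
) -> pd.DataFrame:
    """Entry and immediate-exit behaviour at a dead-end branch.

    For the k-th arrival of each walker at ``junction``, the fraction
    turning into the branch; and among those entries, the fraction back
    at the junction within ``exit_window`` hops of entering (default:
    twice the branch diameter).  Returns a tidy frame indexed by the
    arrival index k.

    With ``require_prior_full_visit`` only arrivals at which every
    branch room had already been visited are counted — the regime in
    which re-entering the branch can serve no exploratory purpose, so
    heading straight back signals that the branch is remembered.
    """
    import networkx as nx

    branch = set(branch_rooms)
    if junction in branch:
        raise ValueError("junction must not be part of the branch")
    sub = env.graph.subgraph(branch)
    if not branch or not nx.is_connected(sub):
        raise ValueError("branch rooms must form a connected subgraph")
    entries = [r for r in branch if env.graph.has_edge(junction, r)]
    if not entries:
        raise ValueError("junction is not adjacent to the branch")
    outside = {
        n
        for r in branch
        for n in env.graph.neighbors(r)
        if n not in branch and n != junction
    }
    if outside:
        raise ValueError(f"branch is not dead-end; leaks to {sorted(outside)}")
    if exit_window is None:
        diameter = nx.diameter(sub) if len(branch) > 1 else 1
        exit_window = 2 * diameter

    rows: dict[int, dict[str, int]] = {}
    for traj in corpus:
        if phase_filter is not None:
            sliced = traj.phase_slice(phase_filter)
            if sliced is None:
                continue
            traj = sliced
        k = 0
        seen: set[str] = set()
        for i in range(traj.n_steps - 1):
            seen.add(traj.rooms[i])
            if traj.rooms[i] != junction:
                continue
            k += 1
            if require_prior_full_visit and not branch <= seen:
                continue
            row = rows.setdefault(k, {"arrivals": 0, "entries": 0, "exits": 0})
            row["arrivals"] += 1
            if traj.rooms[i + 1] in branch:
                row["entries"] += 1
                # hops spent inside before reappearing at the junction
                for j in range(i + 2, min(i + 2 + exit_window, traj.n_steps)):
                    if traj.rooms[j] == junction:
                        row["exits"] += 1
                        break
    records = []
    for k in sorted(rows):
        row = rows[k]
        records.append(
            {
                "visit_index": k,
                "arrivals": row["arrivals"],
                "entries": row["entries"],
                "entry_fraction": row["entries"] / row["arrivals"],
                "exits_within_window": row["exits"],
                "exit_fraction": (row["exits"] / row["entries"]) if row["entries"] else np.nan,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "visit_index",
            "arrivals",
            "entries",
            "entry_fraction",
            "exits_within_window",
            "exit_fraction",
        ],
    )
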