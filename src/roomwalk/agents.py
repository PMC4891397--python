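"""Step rules and runners for the three exploring-agent families.

* **Unbiased random walker** — the next room is chosen uniformly among
  the neighbours of the current room.
* **Agent with perfect m-step memory** — a biased walker that avoids
  moving back to any room in its m-step memory window (the window holds
  the last m occupied rooms, current room included).  When every
  neighbour is remembered, it scans its window for the nearest
  *unexplored junction* — a remembered room with at least one neighbour
  outside the window — and retraces its remembered path to it one hop
  per step; the unexplored direction is drawn only on arrival.  If no
  such junction is remembered, it falls back to a uniform neighbour
  choice.
* **m-th-order Markov agent** — samples the next room from the
  conditional distribution estimated from a trajectory corpus
  (:mod:`roomwalk.markov`), with order back-off.

Runs are driven by a :class:`TerminationRule` (run to full coverage, to
a target coverage, or for a fixed number of hops) with a safety cap, and
are fully reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .environment import EnvironmentGraph
from .markov import ContextTable, next_room_distribution
from .trajectories import Trajectory

#: nominal seconds per hop used to timestamp simulated trajectories
HOP_SECONDS = 6.0


@dataclass
class TerminationRule:
    """When a simulated walk stops.

    mode ``full_coverage``: stop at 100 % coverage (or at ``cap`` hops,
    flagged truncated).  ``target_coverage``: stop once coverage >=
    ``threshold`` percent.  ``fixed_hops``: stop after exactly
    ``threshold`` hops.
    """

    mode: str
    threshold: float | None = None
    cap: int = 100_000

    def __post_init__(self) -> None:
        if self.mode not in ("full_coverage", "target_coverage", "fixed_hops"):
            raise ValueError(f"unknown termination mode {self.mode!r}")
        if self.mode == "fixed_hops":
            if self.threshold is None or self.threshold < 0 or self.threshold != int(self.threshold):
                raise ValueError("fixed_hops requires a non-negative integer threshold")
            if self.cap < self.threshold:
                raise ValueError("cap must be >= fixed hop count")
        elif self.mode == "target_coverage":
            if self.threshold is None or not 0 < self.threshold <= 100:
                raise ValueError("target_coverage requires threshold in (0, 100]")
        if self.cap <= 0:
            raise ValueError("cap must be positive")


@dataclass
class AgentState:
    """Mutable walk state shared by all step rules."""

    current: str
    memory: list[str]  # last <= m occupied rooms, oldest first, current last
    visited: set[str]
    hops: int
    route: list[str] = field(default_factory=list)  # pending backtrack hops
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def _weighted_choice(
    rng: np.random.Generator,
    options: Sequence[str],
    weights: Sequence[float] | None = None,
) -> str:
    """One option per single uniform draw; equal weights reduce exactly
    to the unweighted rule, so degenerate parameterisations consume the
    same random stream."""
    r = rng.random()
    if weights is None:
        return options[int(r * len(options))]
    total = sum(weights)
    acc = 0.0
    for opt, w in zip(options, weights):
        acc += w / total
        if r < acc:
            return opt
    return options[-1]


def step_random_walker(state: AgentState, env: EnvironmentGraph) -> str:
    nbrs = env.neighbors(state.current)
    if not nbrs:
        raise ValueError(f"room {state.current!r} is isolated")
    return _weighted_choice(state.rng, nbrs)


def _as_route(env: EnvironmentGraph, cur: str, waypoints: Sequence[str]) -> list[str]:
    """Hop-by-hop route from ``cur`` through ``waypoints``, bridging any
    non-adjacent consecutive pair with a shortest path (gaps only arise
    when memory entries have been forgotten)."""
    adj = env.adjacency()
    route: list[str] = []
    prev = cur
    for w in waypoints:
        if w == prev:
            continue
        if w in adj[prev]:
            route.append(w)
        else:
            route.extend(nx.shortest_path(env.graph, prev, w)[1:])
        prev = w
    return route


def memory_choice(
    state: AgentState,
    env: EnvironmentGraph,
    weight_fn: Callable[[str, Sequence[str]], Sequence[float] | None] | None = None,
) -> str:
    """Core m-step-memory decision; ``weight_fn(current, options)`` may
    bias the unexplored-neighbour choice (used by the synthetic players'
    staircase aversion).

    When every neighbour is remembered, the walker retraces its
    remembered path to the nearest junction with an unexplored
    direction, one hop per step along a fixed route.  The unexplored
    direction itself is *not* chosen in advance: on arrival at the
    junction its out-of-window neighbours are unexplored options and
    rule (i) draws among them, so no decision variable outlives the
    memory window.
    """
    adj = env.adjacency()
    cur = state.current
    nbrs = adj[cur]
    if not nbrs:
        raise ValueError(f"room {cur!r} is isolated")
    if state.route:
        return state.route.pop(0)
    window = set(state.memory)
    fresh = [n for n in nbrs if n not in window]
    if fresh:
        weights = weight_fn(cur, fresh) if weight_fn is not None else None
        return _weighted_choice(state.rng, fresh, weights)
    # scan the remembered path, most recent first, for the nearest
    # junction with an unexplored direction
    mem = state.memory
    for i in range(len(mem) - 2, -1, -1):
        if any(n not in window for n in adj[mem[i]]):
            route = _as_route(env, cur, list(reversed(mem[i:-1])))
            if route:
                state.route = route
                return state.route.pop(0)
    return _weighted_choice(state.rng, nbrs)


def step_memory_agent(
    state: AgentState, m: int, env: EnvironmentGraph
) -> str:
    """Perfect m-step-memory step (m=0 degenerates to the random walker)."""
    if m < 0:
        raise ValueError("memory length m must be >= 0")
    return memory_choice(state, env)


def step_markov_agent(
    state: AgentState,
    table: ContextTable,
    env: EnvironmentGraph,
    trail: Sequence[str],
) -> str:
    """Sample the next room from the corpus-estimated distribution."""
    dist = next_room_distribution(table, trail, env)
    options = list(dist)
    return _weighted_choice(state.rng, options, [dist[o] for o in options])


def advance(state: AgentState, nxt: str, m: int) -> None:
    """Commit a hop: update position, memory window and visited set."""
    state.current = nxt
    state.visited.add(nxt)
    state.hops += 1
    if m > 0:
        state.memory.append(nxt)
        if len(state.memory) > m:
            del state.memory[0]


def _rule_satisfied(rule: TerminationRule, state: AgentState, n_rooms: int) -> bool:
    if rule.mode == "fixed_hops":
        return state.hops >= rule.threshold
    cov = 100.0 * len(state.visited) / n_rooms
    if rule.mode == "full_coverage":
        return cov >= 100.0
    return cov >= rule.threshold  # target_coverage


def run_agent(
    kind: str,
    env: EnvironmentGraph,
    rule: TerminationRule,
    seed: int | np.random.SeedSequence | np.random.Generator,
    start: str | None = None,
    m: int | None = None,
    table: ContextTable | None = None,
    player_id: str | None = None,
) -> Trajectory:
    """Generate one trajectory with the given agent and stopping rule.

    ``kind`` is ``"random"``, ``"memory"`` (requires ``m``) or
    ``"markov"`` (requires ``table``).  Identical seeds and parameters
    yield identical trajectories.
    """
    if kind not in ("random", "memory", "markov"):
        raise ValueError(f"unknown agent kind {kind!r}")
    if kind == "memory" and (m is None or m < 0):
        raise ValueError("memory agent requires m >= 0")
    if kind == "markov" and table is None:
        raise ValueError("markov agent requires a context table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = start if start is not None else env.default_start()
    if start not in env.rooms:
        raise ValueError(f"start room {start!r} not in environment")
    mem_len = m if kind == "memory" else 0
    state = AgentState(
        current=start,
        memory=[start] if mem_len > 0 else [],
        visited={start},
        hops=0,
        rng=rng,
    )
    trail = [start]
    truncated = False
    n_rooms = env.n_rooms
    while not _rule_satisfied(rule, state, n_rooms):
        if state.hops >= rule.cap:
            truncated = True
            break
        if kind == "random":
            nxt = step_random_walker(state, env)
        elif kind == "memory":
            nxt = step_memory_agent(state, mem_len, env)
        else:
            nxt = step_markov_agent(state, table, env, trail)
        advance(state, nxt, mem_len)
        trail.append(nxt)
    return Trajectory(
        player_id=player_id or f"{kind}-agent",
        rooms=trail,
        times=[i * HOP_SECONDS for i in range(len(trail))],
        phases=["exploration"] * len(trail),
        truncated=truncated,
    )
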