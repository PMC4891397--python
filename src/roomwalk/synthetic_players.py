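"""Synthetic exploration cohorts with controlled, stated imperfections.

No public corpus of human game logs exists for this kind of experiment,
so this module generates one: a cohort of walkers built on the perfect
m-step-memory agent, degraded and biased in four interpretable ways so
every analysis stage — especially memory-depth recovery from a Markov
order sweep — has realistic, recoverable structure to find.

Per hop, a synthetic player

1. *forgets*: each remembered room is independently dropped from the
   memory window with probability ``p_forget``;
2. *reverses*: with a probability depending on the class of the current
   location (straight corridor, corner, staircase, two-door room with a
   visible or hidden far door), it goes back through the door it came
   in by;
3. *prunes*: if it has just stepped from a junction into a dead-end
   branch whose rooms it has all visited before, it heads straight back
   with probability ``p_prune`` (a signature of longer-term memory);
4. otherwise it chooses like the m-step memory agent, except that while
   an unvisited same-floor option remains, staircase options are
   down-weighted by ``floor_aversion`` (the floor-first strategy).

With forgetting, reversals and biases all switched off, the generator
is seed-for-seed identical to the perfect memory agent (and, at
``m_mem=0``, to the unbiased random walker).

Walks terminate at a target coverage, 89 % by default, emulating a
checkpoint design that forces most of the building to be seen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .agents import HOP_SECONDS, AgentState, memory_choice
from .environment import EnvironmentGraph, dead_end_branches
from .metrics import (
    ROOM_TWO_DOOR_HIDDEN,
    ROOM_TWO_DOOR_VISIBLE,
    SIMPLE_CORNER,
    SIMPLE_CORRIDOR,
    STAIRCASE,
    classify_rooms,
)
from .trajectories import Trajectory, TrajectoryCorpus

#: default per-class probabilities of turning back at a decision point
DEFAULT_REVERSAL_PROFILE: dict[str, float] = {
    SIMPLE_CORRIDOR: 0.05,
    STAIRCASE: 0.05,
    SIMPLE_CORNER: 0.08,
    ROOM_TWO_DOOR_VISIBLE: 0.20,
    ROOM_TWO_DOOR_HIDDEN: 0.40,
}


@dataclass
class SyntheticCohortParams:
    """Generator settings; the defaults define the emulated cohort:
    44 players with a 7-room memory window, terminating at 89 %
    coverage, with mild forgetting and a floor-first staircase bias."""

    n_players: int = 44
    m_mem: int = 7
    p_forget: float = 0.18
    floor_aversion: float = 0.5
    reversal_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REVERSAL_PROFILE)
    )
    p_prune: float = 0.80
    target_coverage: float = 89.0
    cap: int = 100_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        if self.m_mem < 0:
            raise ValueError("m_mem must be >= 0")
        for name in ("p_forget", "floor_aversion", "p_prune"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.floor_aversion == 0:
            raise ValueError("floor_aversion must be in (0, 1]")
        for cls, p in self.reversal_profile.items():
            if not 0 <= p <= 1:
                raise ValueError(f"reversal_profile[{cls!r}] must be in [0, 1]")
        if not 0 < self.target_coverage <= 100:
            raise ValueError("target_coverage must be in (0, 100]")

    def to_json_obj(self) -> dict:
        return asdict(self)


def generate_player(
    params: SyntheticCohortParams,
    env: EnvironmentGraph,
    seed: int | np.random.SeedSequence,
    start: str | None = None,
    player_id: str = "synthetic",
) -> Trajectory:
    """Generate one synthetic exploration trajectory."""
    rng = np.random.default_rng(seed)
    start = start if start is not None else env.default_start()
    classes = classify_rooms(env)
    # the start room is never part of a prunable pocket: the entrance is
    # where exploration began, not a dead end discovered along the way
    branch_by_entry = {
        (b.junction, e): b.rooms
        for b in dead_end_branches(env)
        if start not in b.rooms
        for e in b.entries
    }
    m = params.m_mem
    state = AgentState(
        current=start,
        memory=[start] if m > 0 else [],
        visited={start},
        hops=0,
        rng=rng,
    )
    trail = [start]
    n_rooms = env.n_rooms
    link_type = env.link_type
    truncated = False
    pending_prune_back: str | None = None

    def weight_fn(cur: str, options):
        if params.floor_aversion >= 1.0:
            return None
        stair = [link_type(cur, o) == "staircase" for o in options]
        if all(stair) or not any(stair):
            return None
        # an unvisited same-floor option exists: damp the staircases
        return [params.floor_aversion if s else 1.0 for s in stair]

    while 100.0 * len(state.visited) / n_rooms < params.target_coverage:
        if state.hops >= params.cap:
            truncated = True
            break
        cur = state.current
        prev = trail[-2] if len(trail) > 1 else None
        # (1) forgetting
        if params.p_forget > 0 and state.memory:
            state.memory = [
                r for r in state.memory if rng.random() >= params.p_forget
            ]
        nxt: str | None = None
        # (2) class-dependent reversal
        if prev is not None:
            p_rev = params.reversal_profile.get(classes.get(cur, ""), 0.0)
            if p_rev > 0 and rng.random() < p_rev:
                nxt = prev
                state.route.clear()
        # (3) dead-end pruning: just entered a fully-visited branch
        if nxt is None and pending_prune_back is not None:
            if params.p_prune > 0 and rng.random() < params.p_prune:
                nxt = pending_prune_back
                state.route.clear()
        # (4) memory-agent choice with staircase aversion
        if nxt is None:
            nxt = memory_choice(state, env, weight_fn)
        branch = branch_by_entry.get((cur, nxt))
        pending_prune_back = (
            cur if (branch is not None and branch <= state.visited) else None
        )
        state.current = nxt
        state.visited.add(nxt)
        state.hops += 1
        if m > 0:
            state.memory.append(nxt)
            if len(state.memory) > m:
                del state.memory[0]
        trail.append(nxt)
    return Trajectory(
        player_id=player_id,
        rooms=trail,
        times=[i * HOP_SECONDS for i in range(len(trail))],
        phases=["exploration"] * len(trail),
        truncated=truncated,
    )


def generate_cohort(
    params: SyntheticCohortParams,
    env: EnvironmentGraph,
    start: str | None = None,
) -> TrajectoryCorpus:
    """Generate ``params.n_players`` trajectories with spawned seeds."""
    trajectories = [
        generate_player(
            params,
            env,
            np.random.SeedSequence((params.master_seed, i)),
            start=start,
            player_id=f"synth-{i:03d}",
        )
        for i in range(params.n_players)
    ]
    return TrajectoryCorpus(trajectories, env, provenance="synthetic")


def cohort_summary(corpus: TrajectoryCorpus) -> dict[str, float]:
    """Mean hops and mean coverage of a cohort."""
    from .trajectories import coverage

    hops = [t.n_hops for t in corpus]
    covs = [coverage(t, corpus.env) for t in corpus]
    return {
        "n_players": len(corpus),
        "mean_hops": float(np.mean(hops)),
        "sd_hops": float(np.std(hops, ddof=1)) if len(hops) > 1 else 0.0,
        "mean_coverage": float(np.mean(covs)),
        "sd_coverage": float(np.std(covs, ddof=1)) if len(covs) > 1 else 0.0,
    }


def write_sidecar(
    params: SyntheticCohortParams,
    summary: Mapping[str, float],
    sink: str | Path | IO[str],
) -> None:
    """JSON sidecar recording generator parameters, seed and summary."""
    obj = {"params": params.to_json_obj(), "summary": dict(summary)}
    text = json.dumps(obj, indent=2) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")
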