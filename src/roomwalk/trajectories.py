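"""Movement logs: trajectories, corpora, movement graphs and coverage.

A trajectory is one walker's ordered sequence of room visits with
timestamps and a phase label per step (``exploration`` or ``testing``).
Consecutive rooms must be adjacent in the governing environment graph; a
*hop* is one such transition, so a trajectory of n steps has n-1 hops.

The directed *movement graph* of a trajectory carries, per ordered room
pair, the list of times at which that transition was taken, plus the
per-room visit counts f(r).  Coverage is the percentage of distinct
rooms visited out of all rooms in the environment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import networkx as nx

from .environment import EnvironmentGraph

PHASES = ("exploration", "testing")


class MovementLogError(ValueError):
    """Raised for malformed movement logs or invalid trajectories."""


@dataclass
class Trajectory:
    """One walker's ordered, timestamped room sequence."""

    player_id: str
    rooms: list[str]
    times: list[float]
    phases: list[str]
    truncated: bool = False

    def __post_init__(self) -> None:
        n = len(self.rooms)
        if n < 1:
            raise MovementLogError(f"player {self.player_id!r}: empty trajectory")
        if len(self.times) != n or len(self.phases) != n:
            raise MovementLogError(
                f"player {self.player_id!r}: rooms/times/phases length mismatch"
            )
        for i in range(1, n):
            if self.times[i] < self.times[i - 1]:
                raise MovementLogError(
                    f"player {self.player_id!r}: time regression at step {i}"
                )
            if self.rooms[i] == self.rooms[i - 1]:
                raise MovementLogError(
                    f"player {self.player_id!r}: repeated room "
                    f"{self.rooms[i]!r} at step {i} (self-loops rejected)"
                )
        for ph in self.phases:
            if ph not in PHASES:
                raise MovementLogError(
                    f"player {self.player_id!r}: unknown phase {ph!r}"
                )

    @property
    def n_steps(self) -> int:
        return len(self.rooms)

    @property
    def n_hops(self) -> int:
        return len(self.rooms) - 1

    def steps(self) -> Iterable[tuple[str, float, str]]:
        return zip(self.rooms, self.times, self.phases)

    def distinct_rooms(self) -> set[str]:
        return set(self.rooms)

    def validate_against(self, env: EnvironmentGraph) -> None:
        adj = env.adjacency()
        for i, room in enumerate(self.rooms):
            if room not in env.rooms:
                raise MovementLogError(
                    f"player {self.player_id!r}: unknown room {room!r} at step {i}"
                )
            if i and self.rooms[i - 1] not in adj[room]:
                raise MovementLogError(
                    f"player {self.player_id!r}: rooms {self.rooms[i - 1]!r} and "
                    f"{room!r} at steps {i - 1}-{i} are not adjacent"
                )

    def phase_slice(self, phase: str) -> "Trajectory | None":
        """Largest contiguous run of steps in ``phase`` (phases are
        contiguous in practice: exploration precedes testing)."""
        best: tuple[int, int] | None = None
        start = None
        for i, ph in enumerate(self.phases + ["_"]):
            if ph == phase and start is None:
                start = i
            elif ph != phase and start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
        if best is None:
            return None
        lo, hi = best
        return Trajectory(
            self.player_id,
            self.rooms[lo:hi],
            self.times[lo:hi],
            self.phases[lo:hi],
            truncated=self.truncated,
        )


@dataclass
class TrajectoryCorpus:
    """A set of trajectories over one environment graph."""

    trajectories: list[Trajectory]
    env: EnvironmentGraph
    provenance: str = "human"  # human | synthetic | agent

    def __post_init__(self) -> None:
        for t in self.trajectories:
            t.validate_against(self.env)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def subset(self, player_ids: Sequence[str]) -> "TrajectoryCorpus":
        wanted = set(player_ids)
        return TrajectoryCorpus(
            [t for t in self.trajectories if t.player_id in wanted],
            self.env,
            self.provenance,
        )


class MovementGraph:
    """Directed graph of one trajectory's transitions with traversal times."""

    def __init__(self, trajectory: Trajectory) -> None:
        self.player_id = trajectory.player_id
        self.graph = nx.DiGraph()
        self.visit_counts: dict[str, int] = {}
        for room in trajectory.rooms:
            self.visit_counts[room] = self.visit_counts.get(room, 0) + 1
            if room not in self.graph:
                self.graph.add_node(room)
        for i in range(1, trajectory.n_steps):
            u, v = trajectory.rooms[i - 1], trajectory.rooms[i]
            if self.graph.has_edge(u, v):
                self.graph.edges[u, v]["times"].append(trajectory.times[i])
            else:
                self.graph.add_edge(u, v, times=[trajectory.times[i]])

    @property
    def n_steps(self) -> int:
        return sum(self.visit_counts.values())

    def f(self, room: str) -> int:
        """Visit count f(r)."""
        return self.visit_counts.get(room, 0)

    def traversal_times(self, u: str, v: str) -> list[float]:
        return list(self.graph.edges[u, v]["times"])


def build_movement_graph(trajectory: Trajectory) -> MovementGraph:
    return MovementGraph(trajectory)


def coverage(
    visited: Trajectory | Iterable[str], env: EnvironmentGraph
) -> float:
    """Percentage of distinct rooms visited out of all rooms."""
    if env.n_rooms == 0:
        raise ValueError("coverage undefined on an empty environment")
    if isinstance(visited, Trajectory):
        rooms = visited.distinct_rooms()
    else:
        rooms = set(visited)
    unknown = rooms - set(env.rooms)
    if unknown:
        raise ValueError(f"rooms not in environment: {sorted(unknown)}")
    return 100.0 * len(rooms) / env.n_rooms


# -- CSV I/O -------------------------------------------------------------

_HEADER = ["player_id", "room_id", "t", "phase"]


def read_movement_log(
    source: str | Path | IO[str], env: EnvironmentGraph, provenance: str = "human"
) -> TrajectoryCorpus:
    """Read a movement log (CSV: player_id,room_id,t,phase)."""
    if hasattr(source, "read"):
        rows = list(csv.reader(source))  # type: ignore[arg-type]
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    if not rows or rows[0] != _HEADER:
        raise MovementLogError(
            f"expected header {','.join(_HEADER)!r}, got {rows[0] if rows else 'empty file'!r}"
        )
    per_player: dict[str, tuple[list[str], list[float], list[str]]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise MovementLogError(f"row {lineno}: expected 4 fields, got {len(row)}")
        pid, room, t_raw, phase = row
        if room not in env.rooms:
            raise MovementLogError(f"row {lineno}: unknown room {room!r}")
        try:
            t = float(t_raw)
        except ValueError:
            raise MovementLogError(f"row {lineno}: bad timestamp {t_raw!r}") from None
        bucket = per_player.setdefault(pid, ([], [], []))
        if bucket[0]:
            if t < bucket[1][-1]:
                raise MovementLogError(f"row {lineno}: time regression for {pid!r}")
            if room == bucket[0][-1]:
                raise MovementLogError(
                    f"row {lineno}: repeated room {room!r} for {pid!r}"
                )
            if bucket[0][-1] not in env.adjacency()[room]:
                raise MovementLogError(
                    f"row {lineno}: rooms {bucket[0][-1]!r} and {room!r} "
                    f"are not adjacent"
                )
        bucket[0].append(room)
        bucket[1].append(t)
        bucket[2].append(phase)
    trajectories = [
        Trajectory(pid, rooms, times, phases)
        for pid, (rooms, times, phases) in per_player.items()
    ]
    return TrajectoryCorpus(trajectories, env, provenance)


def write_movement_log(
    corpus: TrajectoryCorpus, sink: str | Path | IO[str]
) -> None:
    """Write a corpus back to CSV; inverts :func:`read_movement_log`."""

    def _write(fh) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_HEADER)
        for t in corpus.trajectories:
            for room, time, phase in t.steps():
                w.writerow([t.player_id, room, format(time, "g"), phase])

    if hasattr(sink, "write"):
        _write(sink)  # type: ignore[arg-type]
    else:
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
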