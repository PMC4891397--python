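"""m-th-order Markov estimation of next-room behaviour from a corpus.

The next room visited by a walker is modelled as depending only on the
last m rooms of its path.  The conditional distribution is estimated by
counting: among all contiguous length-(m+1) room windows in the corpus
whose first m rooms equal the walker's recent path, the probability of
next room r is the proportion of windows ending in r.

When a context has never been observed, the query *backs off* to the
order-(m-1) suffix, recursing down to order 1; if even the current room
was never seen, the distribution is uniform over its neighbours in the
environment graph, so a simulated agent always has a total sampling
rule.  Lower-order tables are derived lazily from the same corpus so
the whole back-off chain shares one provenance.

Because windows come from corpus trajectories whose consecutive rooms
are adjacent, every room with positive probability is a neighbour of the
current room at every back-off level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

from .environment import EnvironmentGraph
from .trajectories import TrajectoryCorpus

Context = tuple[str, ...]


@dataclass
class ContextTable:
    """Next-room counts per length-m context, with lazy lower orders."""

    order: int
    counts: dict[Context, dict[str, int]]
    provenance: str = "unknown"
    n_trajectories: int = 0
    phase_filter: str | None = "exploration"
    _corpus: TrajectoryCorpus | None = field(default=None, repr=False)
    _lower: "ContextTable | None" = field(default=None, repr=False)

    def lower_order(self) -> "ContextTable | None":
        """Order-(m-1) table over the same corpus, built on first use."""
        if self.order <= 1 or self._corpus is None:
            return None
        if self._lower is None:
            self._lower = build_context_table(
                self._corpus, self.order - 1, phase_filter=self.phase_filter
            )
        return self._lower

    @property
    def n_contexts(self) -> int:
        return len(self.counts)

    def to_json_obj(self) -> dict:
        return {
            "order": self.order,
            "provenance": self.provenance,
            "n_trajectories": self.n_trajectories,
            "phase_filter": self.phase_filter,
            "contexts": [
                {"path": list(ctx), "next": dict(sorted(nxt.items()))}
                for ctx, nxt in sorted(self.counts.items())
            ],
        }

    def write_json(self, sink: str | Path | IO[str]) -> None:
        text = json.dumps(self.to_json_obj(), indent=2) + "\n"
        if hasattr(sink, "write"):
            sink.write(text)  # type: ignore[union-attr]
        else:
            Path(sink).write_text(text, encoding="utf-8")

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ContextTable":
        return cls(
            order=int(obj["order"]),
            counts={
                tuple(rec["path"]): {k: int(v) for k, v in rec["next"].items()}
                for rec in obj["contexts"]
            },
            provenance=obj.get("provenance", "unknown"),
            n_trajectories=int(obj.get("n_trajectories", 0)),
            phase_filter=obj.get("phase_filter"),
        )

    @classmethod
    def read_json(cls, source: str | Path | IO[str]) -> "ContextTable":
        if hasattr(source, "read"):
            return cls.from_json_obj(json.load(source))  # type: ignore[arg-type]
        with open(source, encoding="utf-8") as fh:
            return cls.from_json_obj(json.load(fh))


def build_context_table(
    corpus: TrajectoryCorpus,
    m: int,
    phase_filter: str | None = "exploration",
) -> ContextTable:
    """Count every contiguous length-(m+1) window across the corpus.

    Windows never span trajectory boundaries, and with a phase filter
    they never span a phase change either.  Estimation defaults to the
    exploration phase, the phase in which unguided search happens.
    """
    if m < 1:
        raise ValueError(f"Markov order must be >= 1, got {m}")
    if len(corpus) == 0:
        raise ValueError("cannot estimate from an empty corpus")
    counts: dict[Context, dict[str, int]] = {}
    for traj in corpus:
        if phase_filter is None:
            segments = [traj.rooms]
        else:
            sliced = traj.phase_slice(phase_filter)
            segments = [sliced.rooms] if sliced is not None else []
        for rooms in segments:
            for i in range(len(rooms) - m):
                ctx = tuple(rooms[i : i + m])
                nxt = rooms[i + m]
                counts.setdefault(ctx, {}).setdefault(nxt, 0)
                counts[ctx][nxt] += 1
    return ContextTable(
        order=m,
        counts=counts,
        provenance=corpus.provenance,
        n_trajectories=len(corpus),
        phase_filter=phase_filter,
        _corpus=corpus,
    )


def next_room_distribution(
    table: ContextTable,
    recent_path: Sequence[str],
    env: EnvironmentGraph,
) -> dict[str, float]:
    """Conditional next-room distribution with order back-off.

    The length-m suffix of ``recent_path`` is looked up; on a miss the
    query recurses to the lazily built order-(m-1) table, down to order
    1, and finally to a uniform distribution over the current room's
    neighbours.  The returned map always sums to 1.
    """
    if not recent_path:
        raise ValueError("recent_path must be non-empty")
    current = recent_path[-1]
    if current not in env.rooms:
        raise ValueError(f"room {current!r} not in environment")
    t: ContextTable | None = table
    while t is not None:
        if len(recent_path) >= t.order:
            ctx = tuple(recent_path[-t.order :])
            hit = t.counts.get(ctx)
            if hit:
                total = sum(hit.values())
                return {room: c / total for room, c in sorted(hit.items())}
        t = t.lower_order()
    nbrs = env.neighbors(current)
    if not nbrs:
        raise ValueError(f"room {current!r} has no neighbours")
    p = 1.0 / len(nbrs)
    return {room: p for room in nbrs}
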