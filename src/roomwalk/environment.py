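"""Multi-floor room graphs: the arenas that exploring agents move on.

A building is modelled as an undirected graph whose nodes are rooms,
corridors and staircase landings, and whose edges are doors, corridor
links or staircases.  Staircase edges are the only edges allowed to join
rooms on different (adjacent) floors.  Planar coordinates are metres
within a floor; the vertical coordinate of a room is ``floor *
floor_height``, which only matters for the radius-of-gyration statistic.

Two graphs ship with the package as JSON fixtures:

* ``fig3`` — a five-node star used for worked examples: rooms C, D and E
  hanging off corridor B, with corridor A at the far end.
* ``palace44`` — a canonical 44-room, three-floor palace whose structure
  satisfies every published fact about the game environment it emulates
  (four staircases from the ground floor up, a single staircase to the
  top floor, a dead-end dorm corridor with rooms D1/D2 off the Block A
  main corridor, and Block B reachable on-floor only through DB2 and The
  Lounge).  The full adjacency beyond those facts is a frozen,
  documented approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx

CATEGORIES = frozenset({"room", "corridor", "staircase_landing"})
LINK_TYPES = frozenset({"door", "corridor", "staircase"})

#: default vertical spacing between floors, metres
DEFAULT_FLOOR_HEIGHT = 4.0


class EnvironmentFormatError(ValueError):
    """Raised when an environment file is malformed or violates invariants."""


@dataclass
class Room:
    """A node of the environment graph.

    ``door_visibility`` maps ``(from_neighbour, to_neighbour)`` pairs to
    ``"visible"`` or ``"hidden"`` and records whether the far door of a
    two-door room can be seen from the entry door.  ``corner`` marks a
    degree-2 corridor as a corner rather than a straight segment; both
    are behavioural annotations, not geometry.
    """

    id: str
    name: str
    floor: int
    x: float
    y: float
    category: str
    block: str | None = None
    corner: bool = False
    door_visibility: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise EnvironmentFormatError(f"room {self.id!r}: floor must be >= 0")
        if self.category not in CATEGORIES:
            raise EnvironmentFormatError(
                f"room {self.id!r}: unknown category {self.category!r}"
            )


class EnvironmentGraph:
    """An attributed, undirected, connected multi-floor room graph."""

    def __init__(
        self,
        rooms: Iterable[Room],
        edges: Iterable[tuple[str, str, str]],
        floor_height: float = DEFAULT_FLOOR_HEIGHT,
        start: str | None = None,
    ) -> None:
        if floor_height <= 0:
            raise EnvironmentFormatError("floor_height must be positive")
        self.rooms: dict[str, Room] = {}
        for r in rooms:
            if r.id in self.rooms:
                raise EnvironmentFormatError(f"duplicate room id {r.id!r}")
            self.rooms[r.id] = r
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.rooms)
        for u, v, link_type in edges:
            for end in (u, v):
                if end not in self.rooms:
                    raise EnvironmentFormatError(
                        f"edge ({u!r}, {v!r}) references undeclared room {end!r}"
                    )
            if link_type not in LINK_TYPES:
                raise EnvironmentFormatError(
                    f"edge ({u!r}, {v!r}): unknown link_type {link_type!r}"
                )
            if u == v:
                raise EnvironmentFormatError(f"self-loop on room {u!r}")
            self.graph.add_edge(u, v, link_type=link_type)
        self.floor_height = float(floor_height)
        if start is not None and start not in self.rooms:
            raise EnvironmentFormatError(f"start room {start!r} not in graph")
        self.start = start
        self._adjacency: dict[str, tuple[str, ...]] | None = None
        for room in self.rooms.values():
            for pair in room.door_visibility:
                for nbr in pair:
                    if not self.graph.has_edge(room.id, nbr):
                        raise EnvironmentFormatError(
                            f"door_visibility at {room.id!r} references "
                            f"non-incident edge to {nbr!r}"
                        )

    # -- queries ---------------------------------------------------------

    @property
    def n_rooms(self) -> int:
        return len(self.rooms)

    def room_ids(self) -> list[str]:
        return sorted(self.rooms)

    def adjacency(self) -> dict[str, tuple[str, ...]]:
        """Neighbour lists, sorted for deterministic iteration."""
        if self._adjacency is None:
            self._adjacency = {
                n: tuple(sorted(self.graph.neighbors(n))) for n in self.graph
            }
        return self._adjacency

    def neighbors(self, room: str) -> tuple[str, ...]:
        return self.adjacency()[room]

    def degree(self, room: str) -> int:
        return len(self.adjacency()[room])

    def link_type(self, u: str, v: str) -> str:
        return self.graph.edges[u, v]["link_type"]

    def floor_of(self, room: str) -> int:
        return self.rooms[room].floor

    def position3d(self, room: str) -> tuple[float, float, float]:
        r = self.rooms[room]
        return (r.x, r.y, r.floor * self.floor_height)

    def floors(self) -> list[int]:
        return sorted({r.floor for r in self.rooms.values()})

    def staircase_edges(self) -> list[tuple[str, str]]:
        return sorted(
            tuple(sorted((u, v)))
            for u, v, d in self.graph.edges(data=True)
            if d["link_type"] == "staircase"
        )

    def default_start(self) -> str:
        return self.start if self.start is not None else self.room_ids()[0]


# -- validation ----------------------------------------------------------


def validate_environment(env: EnvironmentGraph) -> list[str]:
    """Return a list of invariant violations; empty iff the graph is valid."""
    report: list[str] = []
    if env.n_rooms and not nx.is_connected(env.graph):
        n_comp = nx.number_connected_components(env.graph)
        report.append(f"graph is disconnected ({n_comp} components)")
    for u, v, d in env.graph.edges(data=True):
        fu, fv = env.floor_of(u), env.floor_of(v)
        if d["link_type"] == "staircase":
            if abs(fu - fv) != 1:
                report.append(
                    f"staircase edge ({u}, {v}) joins floors {fu} and {fv}, "
                    "which are not adjacent"
                )
        elif fu != fv:
            report.append(
                f"{d['link_type']} edge ({u}, {v}) crosses floors {fu} and {fv}"
            )
    if env.floor_height <= 0:
        report.append("floor_height must be positive")
    return report


# -- dead-end branches ---------------------------------------------------


@dataclass(frozen=True)
class DeadEndBranch:
    """A small subgraph connected to the rest of the building only via
    ``junction``; ``entries`` are the branch rooms adjacent to it."""

    junction: str
    rooms: frozenset[str]
    entries: tuple[str, ...]


def dead_end_branches(
    env: EnvironmentGraph, max_size: int = 4
) -> list[DeadEndBranch]:
    """Enumerate dead-end pockets: components that hang off a single node.

    Staircase landings are never part of a branch (a staircase always
    leads somewhere) and branches larger than ``max_size`` rooms are not
    treated as prunable pockets.
    """
    out: list[DeadEndBranch] = []
    for junction in sorted(env.graph):
        sub = env.graph.subgraph(n for n in env.graph if n != junction)
        comps = sorted(nx.connected_components(sub), key=len)
        if len(comps) < 2:
            continue
        for comp in comps[:-1]:  # everything but the largest remainder
            if len(comp) > max_size:
                continue
            if any(env.rooms[r].category == "staircase_landing" for r in comp):
                continue
            entries = tuple(sorted(r for r in comp if env.graph.has_edge(junction, r)))
            out.append(DeadEndBranch(junction, frozenset(comp), entries))
    return out


# -- I/O -----------------------------------------------------------------


def _room_to_record(r: Room) -> dict:
    rec: dict = {
        "id": r.id,
        "name": r.name,
        "floor": r.floor,
        "block": r.block,
        "x": r.x,
        "y": r.y,
        "category": r.category,
    }
    if r.corner:
        rec["corner"] = True
    return rec


def _env_to_obj(env: EnvironmentGraph) -> dict:
    rooms = [_room_to_record(env.rooms[rid]) for rid in env.room_ids()]
    edges = sorted(
        {tuple(sorted((u, v))): d["link_type"] for u, v, d in env.graph.edges(data=True)}.items()
    )
    edge_recs = [
        {"source": u, "target": v, "link_type": lt} for (u, v), lt in edges
    ]
    vis = []
    for rid in env.room_ids():
        for (a, b), val in sorted(env.rooms[rid].door_visibility.items()):
            vis.append({"at": rid, "from_edge": a, "to_edge": b, "visibility": val})
    obj: dict = {"floor_height": env.floor_height}
    if env.start is not None:
        obj["start"] = env.start
    obj["rooms"] = rooms
    obj["edges"] = edge_recs
    if vis:
        obj["door_visibility"] = vis
    return obj


def write_environment(env: EnvironmentGraph, sink: str | Path | IO[str]) -> None:
    """Write the canonical JSON dialect (round-trips with the reader)."""
    text = json.dumps(_env_to_obj(env), indent=2) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")


def _env_from_obj(obj: Mapping) -> EnvironmentGraph:
    try:
        room_recs = obj["rooms"]
        edge_recs = obj["edges"]
    except KeyError as exc:
        raise EnvironmentFormatError(f"missing top-level key {exc}") from None
    rooms = []
    for rec in room_recs:
        try:
            rooms.append(
                Room(
                    id=rec["id"],
                    name=rec["name"],
                    floor=int(rec["floor"]),
                    block=rec.get("block"),
                    x=float(rec["x"]),
                    y=float(rec["y"]),
                    category=rec["category"],
                    corner=bool(rec.get("corner", False)),
                )
            )
        except KeyError as exc:
            raise EnvironmentFormatError(
                f"room record {rec.get('id', rec)!r} missing attribute {exc}"
            ) from None
    edges = []
    for rec in edge_recs:
        try:
            edges.append((rec["source"], rec["target"], rec["link_type"]))
        except KeyError as exc:
            raise EnvironmentFormatError(
                f"edge record {rec!r} missing attribute {exc}"
            ) from None
    env = EnvironmentGraph(
        rooms,
        edges,
        floor_height=float(obj.get("floor_height", DEFAULT_FLOOR_HEIGHT)),
        start=obj.get("start"),
    )
    for rec in obj.get("door_visibility", []):
        try:
            at, frm, to, val = rec["at"], rec["from_edge"], rec["to_edge"], rec["visibility"]
        except KeyError as exc:
            raise EnvironmentFormatError(
                f"door_visibility record {rec!r} missing attribute {exc}"
            ) from None
        if at not in env.rooms:
            raise EnvironmentFormatError(f"door_visibility at unknown room {at!r}")
        if val not in ("visible", "hidden"):
            raise EnvironmentFormatError(
                f"door_visibility at {at!r}: unknown value {val!r}"
            )
        for nbr in (frm, to):
            if not env.graph.has_edge(at, nbr):
                raise EnvironmentFormatError(
                    f"door_visibility at {at!r} references non-incident edge to {nbr!r}"
                )
        env.rooms[at].door_visibility[(frm, to)] = val
    return env


def _env_from_graphml(source) -> EnvironmentGraph:
    g = nx.read_graphml(source)
    rooms = []
    for node, data in g.nodes(data=True):
        try:
            vis_raw = data.get("door_visibility")
            rooms.append(
                Room(
                    id=str(node),
                    name=data["name"],
                    floor=int(data["floor"]),
                    block=data.get("block") or None,
                    x=float(data["x"]),
                    y=float(data["y"]),
                    category=data["category"],
                    corner=bool(data.get("corner", False)),
                    door_visibility={}
                    if not vis_raw
                    else {
                        (rec["from_edge"], rec["to_edge"]): rec["visibility"]
                        for rec in json.loads(vis_raw)
                    },
                )
            )
        except KeyError as exc:
            raise EnvironmentFormatError(
                f"GraphML node {node!r} missing attribute {exc}"
            ) from None
    edges = []
    for u, v, data in g.edges(data=True):
        if "link_type" not in data:
            raise EnvironmentFormatError(
                f"GraphML edge ({u!r}, {v!r}) missing link_type"
            )
        edges.append((str(u), str(v), data["link_type"]))
    return EnvironmentGraph(
        rooms,
        edges,
        floor_height=float(g.graph.get("floor_height", DEFAULT_FLOOR_HEIGHT)),
        start=g.graph.get("start"),
    )


def write_graphml(env: EnvironmentGraph, sink: str | Path) -> None:
    g = nx.Graph(floor_height=env.floor_height)
    if env.start is not None:
        g.graph["start"] = env.start
    for rid in env.room_ids():
        r = env.rooms[rid]
        attrs = {
            "name": r.name,
            "floor": r.floor,
            "x": r.x,
            "y": r.y,
            "category": r.category,
        }
        if r.block is not None:
            attrs["block"] = r.block
        if r.corner:
            attrs["corner"] = True
        if r.door_visibility:
            attrs["door_visibility"] = json.dumps(
                [
                    {"from_edge": a, "to_edge": b, "visibility": val}
                    for (a, b), val in sorted(r.door_visibility.items())
                ]
            )
        g.add_node(rid, **attrs)
    for u, v, d in env.graph.edges(data=True):
        g.add_edge(u, v, link_type=d["link_type"])
    nx.write_graphml(g, sink)


def load_environment(source: str | Path | IO[str]) -> EnvironmentGraph:
    """Read an environment from GraphML or the package's JSON dialect.

    Format is chosen by file extension (``.graphml`` vs anything else);
    streams are assumed to carry JSON.
    """
    if hasattr(source, "read"):
        env = _env_from_obj(json.load(source))  # type: ignore[arg-type]
    else:
        path = Path(source)
        if path.suffix.lower() == ".graphml":
            env = _env_from_graphml(str(path))
        else:
            with open(path, encoding="utf-8") as fh:
                env = _env_from_obj(json.load(fh))
    problems = validate_environment(env)
    if problems:
        raise EnvironmentFormatError("; ".join(problems))
    return env


# -- packaged fixtures ---------------------------------------------------


def _load_fixture(name: str) -> EnvironmentGraph:
    ref = resources.files("roomwalk.fixtures").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return load_environment(fh)


def fig3_fixture() -> EnvironmentGraph:
    """Five-node star: corridors A-B, rooms C, D, E off B.  Single floor."""
    return _load_fixture("fig3.json")


def palace44_fixture() -> EnvironmentGraph:
    """The 44-room, three-floor palace graph (canonical approximation)."""
    return _load_fixture("palace44.json")


def get_fixture(name: str) -> EnvironmentGraph:
    fixtures = {"fig3": fig3_fixture, "palace44": palace44_fixture}
    try:
        return fixtures[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(fixtures)}"
        ) from None
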