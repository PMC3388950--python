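"""Mode-specific routable graphs built from a road network.

A :class:`RoadNetwork` is a planar graph of junction nodes and directed
links, each carrying a length in metres, a road class (motorway, A, B,
minor, local) and per-mode permissions. :func:`build_mode_graph` restricts
it to one mode and attaches travel times: walking and cycling traverse
every permitted link at a constant speed (motorways and other forbidden
links are removed); cars run at the free-flow speed of the road class,
with left/right turn penalties applied at junctions during routing; the
bus mode reuses the walk graph for access, egress and interchange stages.

Off-network points — zone population-weighted centroids and facilities —
are attached by a single straight "dummy" link to the Euclidean-nearest
permitted node.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .config import ModeConfig

UNREACHABLE = float("inf")


@dataclass
class RoadLink:
    u: Hashable
    v: Hashable
    length_m: float
    road_class: str
    walk: bool = True
    cycle: bool = True
    car: bool = True

    def permits(self, mode: str) -> bool:
        if mode in ("walk", "bus"):
            return self.walk
        if mode == "cycle":
            return self.cycle
        if mode == "car":
            return self.car
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class RoadNetwork:
    """Junction nodes (id -> planar coordinate) and directed links."""

    nodes: dict[Hashable, tuple[float, float]]
    links: list[RoadLink]

    def __post_init__(self):
        for lk in self.links:
            if lk.length_m <= 0:
                raise ValueError(f"link {lk.u}->{lk.v} has non-positive length")
            if lk.u not in self.nodes or lk.v not in self.nodes:
                raise ValueError(f"link {lk.u}->{lk.v} references unknown node")
            if lk.road_class not in ("motorway", "A", "B", "minor", "local"):
                raise ValueError(f"unknown road class {lk.road_class!r}")


@dataclass
class ModeGraph:
    """Directed graph for one mode with per-link distance and travel time.

    Edge attributes: ``length_m`` and ``time_min``; ``dummy`` marks the
    links that attach off-network points.
    """

    mode: str
    graph: nx.DiGraph
    config: ModeConfig
    dummy_nodes: set = field(default_factory=set)

    def coords(self, node) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return (d["x"], d["y"])


def _link_time_min(length_m: float, mode: str, road_class: str, config: ModeConfig) -> float:
    if mode == "car":
        speed = config.freeflow_kmh[road_class]
    else:
        speed = config.speed_kmh
    return (length_m / 1000.0) / speed * 60.0


def build_mode_graph(network: RoadNetwork, config: ModeConfig) -> ModeGraph:
    """Filter the road network to one mode and attach travel times.

    Raises if no link permits the mode (an empty graph would silently make
    everything unreachable).
    """
    mode = config.mode
    g = nx.DiGraph()
    for lk in network.links:
        if not lk.permits(mode):
            continue
        t = _link_time_min(lk.length_m, mode, lk.road_class, config)
        g.add_edge(lk.u, lk.v, length_m=lk.length_m, time_min=t,
                   road_class=lk.road_class, dummy=False)
    if g.number_of_edges() == 0:
        raise ValueError(f"no links permit mode {mode!r}: empty {mode} graph")
    for n in g.nodes:
        x, y = network.nodes[n]
        g.nodes[n]["x"] = x
        g.nodes[n]["y"] = y
    return ModeGraph(mode=mode, graph=g, config=config)


def _id_key(n):
    """Total order over node ids: numbers first (numeric order), then strings."""
    if isinstance(n, bool) or not isinstance(n, (int, float)):
        return (1, str(n))
    return (0, float(n))


def nearest_node(graph: ModeGraph, point: tuple[float, float]):
    """Euclidean-nearest non-dummy node; ties broken by lowest node id."""
    best = None
    px, py = point
    for n in graph.graph.nodes:
        if n in graph.dummy_nodes:
            continue
        x, y = graph.coords(n)
        d = math.hypot(x - px, y - py)
        key = (d, _id_key(n))
        if best is None or key < best[0]:
            best = (key, n, d)
    if best is None:
        raise ValueError("graph has no network nodes")
    return best[1], best[2]


def connect_point(graph: ModeGraph, point_id: Hashable, point: tuple[float, float]) -> Hashable:
    """Attach an off-network point by a dummy link to its nearest node.

    The dummy link's length is the straight-line distance; it is traversed
    at walking speed for walk/bus and at the mode speed otherwise (for car
    the slowest class, a local street, stands in). Modifies the graph in
    place and returns the id of the attached node.
    """
    n, dist = nearest_node(graph, point)
    g = graph.graph
    if point_id in g:
        raise ValueError(f"point id {point_id!r} already in graph")
    g.add_node(point_id, x=point[0], y=point[1])
    graph.dummy_nodes.add(point_id)
    if graph.mode == "car":
        t = _link_time_min(dist, "car", "local", graph.config) if dist > 0 else 0.0
    else:
        t = (dist / 1000.0) / graph.config.walk_speed_kmh * 60.0 if graph.mode == "bus" else (
            (dist / 1000.0) / graph.config.speed_kmh * 60.0
        )
    for a, b in ((point_id, n), (n, point_id)):
        g.add_edge(a, b, length_m=dist, time_min=t, road_class="local", dummy=True)
    return n


def population_weighted_centroid(
    points: Iterable[tuple[tuple[float, float], float]]
) -> tuple[float, float]:
    """Population-weighted mean coordinate of weighted household points."""
    xs, ys, ws = [], [], []
    for (x, y), w in points:
        if w < 0:
            raise ValueError("negative population weight")
        xs.append(x)
        ys.append(y)
        ws.append(w)
    total = float(sum(ws))
    if total <= 0:
        raise ValueError("total population must be positive")
    w = np.asarray(ws, dtype=float)
    return (float(np.dot(xs, w) / total), float(np.dot(ys, w) / total))


def bearing_deg(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Direction of travel p->q in degrees counter-clockwise from east."""
    return math.degrees(math.atan2(q[1] - p[1], q[0] - p[0]))


def turn_movement(
    p_from: tuple[float, float],
    p_at: tuple[float, float],
    p_to: tuple[float, float],
    straight_threshold_deg: float = 30.0,
) -> str:
    """Classify a junction movement as straight / left / right.

    The signed bearing change is wrapped to (-180, 180]; |change| within
    the threshold is straight, a positive (counter-clockwise) change a left
    turn, a negative change a right turn. Degenerate zero-length legs
    (dummy links) count as straight.
    """
    if p_from == p_at or p_at == p_to:
        return "straight"
    delta = bearing_deg(p_at, p_to) - bearing_deg(p_from, p_at)
    delta = (delta + 180.0) % 360.0 - 180.0
    if delta == -180.0:
        delta = 180.0
    if abs(delta) <= straight_threshold_deg:
        return "straight"
    return "left" if delta > 0 else "right"


def apply_turn_penalties(path: Sequence[Hashable], graph: ModeGraph, config: ModeConfig) -> float:
    """Total turn-penalty seconds over a path's interior junctions."""
    pen = dict(config.turn_penalties_s)
    pen.setdefault("straight", 0.0)
    total = 0.0
    for a, b, c in zip(path, path[1:], path[2:]):
        if not graph.graph.has_edge(a, b) or not graph.graph.has_edge(b, c):
            raise ValueError("path is not a walk in the graph")
        move = turn_movement(
            graph.coords(a), graph.coords(b), graph.coords(c), config.straight_threshold_deg
        )
        total += pen.get(move, 0.0)
    return total


def shortest_distance_path(graph: ModeGraph, origin, dest):
    """Minimum-length path with ties broken by the lexicographically
    smallest node-id sequence; returns ``(length_m, path)`` or
    ``(UNREACHABLE, None)``."""
    g = graph.graph
    if origin == dest:
        return 0.0, [origin]
    # Dijkstra keyed on (distance, id-key sequence) so the tie-break is exact.
    heap = [(0.0, (_id_key(origin),), (origin,))]
    done: set = set()
    while heap:
        d, _, path = heapq.heappop(heap)
        u = path[-1]
        if u in done:
            continue
        done.add(u)
        if u == dest:
            return d, list(path)
        for v, attrs in g[u].items():
            if v not in done:
                heapq.heappush(
                    heap,
                    (d + attrs["length_m"], tuple(_id_key(p) for p in path) + (_id_key(v),),
                     path + (v,)),
                )
    return UNREACHABLE, None
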