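"""Road network graphs and fastest/shortest-route computation.

The network is a plain node/edge structure: nodes are geographic points,
edges carry a physical length (m) and a posted speed limit (mph). Edge
travel time is ``length / speed_limit`` in consistent units — no turn
penalties, traffic, or time dependence.

Two routing paths are provided:

* :func:`optimal_route` — exact Dijkstra with a deterministic tie-break
  (among minimum-cost routes, the lexicographically smallest node
  sequence wins). This is the reference implementation used by the
  per-trip metric operations.
* :class:`Router` — a scipy.sparse.csgraph-backed engine that
  precomputes all-pairs distances and predecessors for one criterion.
  It answers the same queries orders of magnitude faster and is what
  the simulator and batch pipeline use; ties are broken by the csgraph
  traversal order rather than lexicographically, so only the minimized
  totals (not the node sequences) are guaranteed to match
  :func:`optimal_route` exactly.
"""

from __future__ import annotations

import csv
import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterator, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .geo import MPH_TO_MPS, GeoPoint, GeoError, haversine_distance, haversine_m

NodeId = Hashable


class NetworkError(ValueError):
    """Structurally invalid road network."""


class NoRouteError(ValueError):
    """Destination unreachable from origin."""


def edge_travel_time_s(length_m: float, speed_limit_mph: float) -> float:
    """Free-flow traversal time of an edge, seconds."""
    return length_m / (speed_limit_mph * MPH_TO_MPS)


@dataclass(frozen=True, slots=True)
class Edge:
    u: NodeId
    v: NodeId
    length_m: float
    speed_limit_mph: float
    bidirectional: bool = True


@dataclass(frozen=True, slots=True)
class Route:
    """A network path with its traversed totals."""

    nodes: tuple
    total_length_m: float
    total_duration_s: float


class RoadNetwork:
    """Graph of geographic nodes joined by speed-limited edges."""

    def __init__(self, nodes: Mapping[NodeId, GeoPoint], edges: Sequence[Edge]):
        if not nodes:
            raise NetworkError("network has no nodes")
        self.nodes: dict[NodeId, GeoPoint] = dict(nodes)
        self.edges: list[Edge] = list(edges)
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise NetworkError(f"edge ({e.u}, {e.v}) references unknown node")
            if not (e.length_m > 0 and math.isfinite(e.length_m)):
                raise NetworkError(f"edge ({e.u}, {e.v}) has nonpositive length")
            if not (e.speed_limit_mph > 0 and math.isfinite(e.speed_limit_mph)):
                raise NetworkError(f"edge ({e.u}, {e.v}) has nonpositive speed limit")
        # adjacency: u -> list of (v, length, duration)
        self._adj: dict[NodeId, list[tuple[NodeId, float, float]]] = {
            n: [] for n in self.nodes
        }
        for e in self.edges:
            dur = edge_travel_time_s(e.length_m, e.speed_limit_mph)
            self._adj[e.u].append((e.v, e.length_m, dur))
            if e.bidirectional:
                self._adj[e.v].append((e.u, e.length_m, dur))

    def directed_edges(self) -> Iterator[tuple[NodeId, NodeId, Edge]]:
        for e in self.edges:
            yield e.u, e.v, e
            if e.bidirectional:
                yield e.v, e.u, e

    def neighbors(self, u: NodeId) -> list[tuple[NodeId, float, float]]:
        """(v, length_m, duration_s) for each edge leaving ``u``."""
        return self._adj[u]

    def incident_edges(self, u: NodeId) -> list[Edge]:
        return [e for e in self.edges if e.u == u or (e.bidirectional and e.v == u)]

    def __len__(self) -> int:
        return len(self.nodes)


def optimal_route(
    net: RoadNetwork,
    origin: NodeId,
    dest: NodeId,
    criterion: str = "time",
) -> Route:
    """Minimum-cost route between two nodes.

    ``criterion="time"`` (the default) minimizes total free-flow travel
    duration — the quickest rather than the shortest route;
    ``criterion="distance"`` minimizes total length. Among equal-cost
    routes the lexicographically smallest node sequence is returned.

    Raises :class:`NoRouteError` when ``dest`` is unreachable.
    ``origin == dest`` yields a zero-length, zero-duration route.
    """
    if criterion not in ("time", "distance"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if origin not in net.nodes or dest not in net.nodes:
        raise NetworkError("origin/dest not in network")
    if origin == dest:
        return Route((origin,), 0.0, 0.0)

    cost_idx = 2 if criterion == "time" else 1
    # best (cost, path) seen per node; equal-cost entries with a
    # lexicographically smaller path are re-expanded so the tie-break is
    # exact, not heap-order dependent.
    best: dict[NodeId, tuple[float, tuple]] = {}
    heap: list[tuple[float, tuple]] = [(0.0, (origin,))]
    while heap:
        cost, path = heapq.heappop(heap)
        u = path[-1]
        cur = best.get(u)
        if cur is not None and (cur[0] < cost or (cur[0] == cost and cur[1] <= path)):
            continue
        best[u] = (cost, path)
        if u == dest:
            break
        for nbr in net.neighbors(u):
            v = nbr[0]
            if v in path:  # positive weights: cycles never help
                continue
            heapq.heappush(heap, (cost + nbr[cost_idx], path + (v,)))

    if dest not in best:
        raise NoRouteError(f"no route from {origin!r} to {dest!r}")
    _, path = best[dest]
    total_len = 0.0
    total_dur = 0.0
    for a, b in zip(path[:-1], path[1:]):
        # cheapest directed edge a->b under the routing criterion
        cands = [nbr for nbr in net.neighbors(a) if nbr[0] == b]
        nbr = min(cands, key=lambda t: t[cost_idx])
        total_len += nbr[1]
        total_dur += nbr[2]
    return Route(path, total_len, total_dur)


def snap_to_network(net: RoadNetwork, p: GeoPoint) -> NodeId:
    """Nearest network node to a point (haversine); ties go to the
    smaller node id."""
    if not net.nodes:
        raise GeoError("cannot snap to an empty network")
    ids = sorted(net.nodes)
    lats = np.array([net.nodes[i].lat for i in ids])
    lons = np.array([net.nodes[i].lon for i in ids])
    d = haversine_m(lats, lons, p.lat, p.lon)
    return ids[int(np.argmin(d))]  # argmin takes first == smallest id


class Router:
    """All-pairs fastest/shortest routing on a fixed network.

    Precomputes the full distance and predecessor matrices once
    (scipy.sparse.csgraph Dijkstra); subsequent queries are dictionary
    lookups plus path reconstruction. ``route_avoiding`` answers
    single-source queries on a copy of the graph with selected directed
    edges disabled — the primitive behind detour simulation.
    """

    def __init__(self, net: RoadNetwork, criterion: str = "time"):
        if criterion not in ("time", "distance"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self.net = net
        self.criterion = criterion
        self.node_ids = sorted(net.nodes)
        self._idx = {n: i for i, n in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.lats = np.array([net.nodes[i].lat for i in self.node_ids])
        self.lons = np.array([net.nodes[i].lon for i in self.node_ids])

        rows, cols, lens, durs = [], [], [], []
        for u, v, e in net.directed_edges():
            rows.append(self._idx[u])
            cols.append(self._idx[v])
            lens.append(e.length_m)
            durs.append(edge_travel_time_s(e.length_m, e.speed_limit_mph))
        self._rows = np.array(rows, dtype=np.int32)
        self._cols = np.array(cols, dtype=np.int32)
        self._lens = np.array(lens)
        self._durs = np.array(durs)
        w = self._durs if criterion == "time" else self._lens
        self._w = w
        self._graph = csr_matrix((w, (self._rows, self._cols)), shape=(n, n))
        # (u_idx, v_idx) -> (length, duration) keeping the cheapest edge
        self._edge_info: dict[tuple[int, int], tuple[float, float]] = {}
        order = np.argsort(w)[::-1]  # ascending overwrite => min kept last
        for k in order:
            self._edge_info[(int(self._rows[k]), int(self._cols[k]))] = (
                float(self._lens[k]),
                float(self._durs[k]),
            )
        self.dist, self.pred = _csgraph_dijkstra(
            self._graph, directed=True, return_predecessors=True
        )

    def node_index(self, node: NodeId) -> int:
        return self._idx[node]

    def _reconstruct(self, pred_row: np.ndarray, i: int, j: int) -> list[int]:
        path = [j]
        while path[-1] != i:
            p = pred_row[path[-1]]
            if p < 0:
                raise NoRouteError("unreachable")
            path.append(int(p))
        path.reverse()
        return path

    def _totals(self, idx_path: list[int]) -> tuple[float, float]:
        tl = td = 0.0
        for a, b in zip(idx_path[:-1], idx_path[1:]):
            L, d = self._edge_info[(a, b)]
            tl += L
            td += d
        return tl, td

    def route(self, origin: NodeId, dest: NodeId) -> Route:
        i, j = self._idx[origin], self._idx[dest]
        if i == j:
            return Route((origin,), 0.0, 0.0)
        if not np.isfinite(self.dist[i, j]):
            raise NoRouteError(f"no route from {origin!r} to {dest!r}")
        idx_path = self._reconstruct(self.pred[i], i, j)
        tl, td = self._totals(idx_path)
        return Route(tuple(self.node_ids[k] for k in idx_path), tl, td)

    def route_avoiding(
        self, origin: NodeId, dest: NodeId, avoid: set[tuple[NodeId, NodeId]]
    ) -> Route | None:
        """Route with the given directed node pairs (both directions of a
        road: pass both) disabled; ``None`` if that disconnects the pair."""
        i, j = self._idx[origin], self._idx[dest]
        w = self._w.copy()
        for (u, v) in avoid:
            mask = (self._rows == self._idx[u]) & (self._cols == self._idx[v])
            w[mask] = np.inf
        g = csr_matrix((w, (self._rows, self._cols)), shape=self._graph.shape)
        dist, pred = _csgraph_dijkstra(
            g, directed=True, indices=i, return_predecessors=True
        )
        if not np.isfinite(dist[j]):
            return None
        idx_path = self._reconstruct(pred, i, j)
        tl, td = self._totals(idx_path)
        return Route(tuple(self.node_ids[k] for k in idx_path), tl, td)

    def snap(self, lat: float, lon: float) -> NodeId:
        d = haversine_m(self.lats, self.lons, lat, lon)
        return self.node_ids[int(np.argmin(d))]

    def snap_many(self, lats: np.ndarray, lons: np.ndarray) -> list[NodeId]:
        out = []
        for la, lo in zip(np.asarray(lats, dtype=float), np.asarray(lons, dtype=float)):
            out.append(self.snap(la, lo))
        return out


# ---------------------------------------------------------------------------
# I/O: CSV edge list and GeoJSON LineString features
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "u", "v", "u_lat", "u_lon", "v_lat", "v_lon",
    "length_m", "speed_limit_mph", "bidirectional",
]


def save_network_csv(net: RoadNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for e in net.edges:
            pu, pv = net.nodes[e.u], net.nodes[e.v]
            w.writerow(
                [e.u, e.v, pu.lat, pu.lon, pv.lat, pv.lon,
                 e.length_m, e.speed_limit_mph, int(e.bidirectional)]
            )


def load_network_csv(path) -> RoadNetwork:
    """Read an edge-list CSV. ``length_m`` may be blank, in which case the
    great-circle distance between the endpoints is used."""
    nodes: dict[NodeId, GeoPoint] = {}
    edges: list[Edge] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            u, v = _coerce_id(row["u"]), _coerce_id(row["v"])
            pu = GeoPoint(float(row["u_lat"]), float(row["u_lon"]))
            pv = GeoPoint(float(row["v_lat"]), float(row["v_lon"]))
            nodes.setdefault(u, pu)
            nodes.setdefault(v, pv)
            raw_len = row.get("length_m") or ""
            length = float(raw_len) if raw_len.strip() else haversine_distance(pu, pv)
            bidi = str(row.get("bidirectional", "1")).strip().lower() not in ("0", "false", "")
            edges.append(Edge(u, v, length, float(row["speed_limit_mph"]), bidi))
    return RoadNetwork(nodes, edges)


def load_network_geojson(path) -> RoadNetwork:
    """Read LineString features carrying the same properties as the CSV
    schema (``u``, ``v``, ``speed_limit_mph``, optional ``length_m`` and
    ``bidirectional``); only two-point LineStrings are supported."""
    with open(path) as fh:
        gj = json.load(fh)
    nodes: dict[NodeId, GeoPoint] = {}
    edges: list[Edge] = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        coords = geom["coordinates"]
        if len(coords) != 2:
            raise NetworkError("only two-point LineString edges are supported")
        props = feat.get("properties", {})
        u, v = _coerce_id(props["u"]), _coerce_id(props["v"])
        pu = GeoPoint(coords[0][1], coords[0][0])  # GeoJSON is lon,lat
        pv = GeoPoint(coords[1][1], coords[1][0])
        nodes.setdefault(u, pu)
        nodes.setdefault(v, pv)
        length = float(props.get("length_m") or haversine_distance(pu, pv))
        bidi = bool(props.get("bidirectional", True))
        edges.append(Edge(u, v, length, float(props["speed_limit_mph"]), bidi))
    return RoadNetwork(nodes, edges)


def _coerce_id(s: str) -> NodeId:
    s = str(s).strip()
    try:
        return int(s)
    except ValueError:
        return s
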