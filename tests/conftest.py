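import numpy as np
import pytest

from wayfind.roads import Edge, RoadNetwork, Router
from wayfind.geo import GeoPoint
from wayfind.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by pipeline-level tests."""
    cfg = SimulationConfig(seed=20240915, n_drivers=16, trips_per_driver=40)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def grid_net():
    cfg = SimulationConfig(seed=3, grid_rows=8, grid_cols=8)
    from wayfind.simulate import make_grid_network

    return make_grid_network(cfg, np.random.default_rng(3))


@pytest.fixture()
def line_net():
    """Three collinear equatorial nodes 1 km apart, one slow middle
    bypass: a minimal network for ratio tests."""
    km = 1.0 / 111.19492664455873  # ~1 km in degrees at the equator
    nodes = {
        0: GeoPoint(0.0, 0.0),
        1: GeoPoint(0.0, km),
        2: GeoPoint(0.0, 2 * km),
    }
    edges = [
        Edge(0, 1, 1000.0, 30.0),
        Edge(1, 2, 1000.0, 30.0),
    ]
    return RoadNetwork(nodes, edges)


def random_small_network(rng, n_max=6):
    """Random connected directed network with <= n_max nodes; used by
    the enumeration-oracle routing tests."""
    import itertools

    n = int(rng.integers(2, n_max + 1))
    nodes = {
        i: GeoPoint(float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1)))
        for i in range(n)
    }
    edges = []
    # random spanning chain guarantees connectivity, then extra edges
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        edges.append(
            Edge(int(a), int(b), float(rng.uniform(100, 2000)),
                 float(rng.uniform(10, 60)), bidirectional=True)
        )
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < 0.35:
            edges.append(
                Edge(u, v, float(rng.uniform(100, 2000)),
                     float(rng.uniform(10, 60)),
                     bidirectional=bool(rng.random() < 0.7))
            )
    return RoadNetwork(nodes, edges)


def enumerate_optimal(net, origin, dest, criterion):
    """Brute-force routing oracle: exhaustive simple-path enumeration
    (networkx), minimizing (cost, node sequence)."""
    import networkx as nx
    from wayfind.roads import edge_travel_time_s

    g = nx.DiGraph()
    for u, v, e in net.directed_edges():
        w = e.length_m if criterion == "distance" else edge_travel_time_s(
            e.length_m, e.speed_limit_mph
        )
        # parallel edges: keep the cheaper
        if g.has_edge(u, v):
            if w >= g[u][v]["w"]:
                continue
        g.add_edge(u, v, w=w)
    best = None
    for path in nx.all_simple_paths(g, origin, dest):
        cost = sum(g[a][b]["w"] for a, b in zip(path[:-1], path[1:]))
        key = (cost, tuple(path))
        if best is None or key < best:
            best = key
    return best
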