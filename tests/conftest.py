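import numpy as np
import pytest

from modaccess.config import ModeConfig, RegionConfig
from modaccess.network import RoadLink, RoadNetwork, build_mode_graph
from modaccess.synthetic import generate_region


@pytest.fixture(scope="session")
def region_bundle():
    """One 50-zone synthetic region shared across tests."""
    return generate_region(RegionConfig(seed=1, n_zones=50))


def make_network(nodes, edges, road_class="local", **perm):
    """Small test road network; ``edges`` are (u, v, length_m) added in both
    directions unless ``oneway`` appears in perm."""
    oneway = perm.pop("oneway", False)
    links = []
    for u, v, L in edges:
        links.append(RoadLink(u=u, v=v, length_m=L, road_class=road_class, **perm))
        if not oneway:
            links.append(RoadLink(u=v, v=u, length_m=L, road_class=road_class, **perm))
    return RoadNetwork(nodes=dict(nodes), links=links)


def random_geometric_network(rng: np.random.Generator, n_nodes=None, min_len=150.0):
    """Connected random planar-ish network for oracle tests (<= 8 nodes)."""
    n = int(n_nodes or rng.integers(4, 9))
    while True:
        pts = rng.uniform(0, 2000, size=(n, 2))
        edges = []
        seen = set()
        # random spanning tree first, then extra edges
        order = rng.permutation(n)
        for i in range(1, n):
            u, v = int(order[i - 1]), int(order[i])
            seen.add((min(u, v), max(u, v)))
        extra = rng.integers(0, n)
        for _ in range(extra):
            u, v = rng.integers(0, n, size=2)
            if u != v:
                seen.add((int(min(u, v)), int(max(u, v))))
        ok = True
        for u, v in sorted(seen):
            L = float(np.hypot(*(pts[u] - pts[v])))
            if L < min_len:
                ok = False
                break
            edges.append((u, v, L))
        if ok:
            break
    nodes = {i: (float(pts[i][0]), float(pts[i][1])) for i in range(n)}
    classes = ["A", "B", "minor", "local"]
    links = []
    for u, v, L in edges:
        rc = classes[int(rng.integers(0, len(classes)))]
        links.append(RoadLink(u=u, v=v, length_m=L, road_class=rc))
        links.append(RoadLink(u=v, v=u, length_m=L, road_class=rc))
    return RoadNetwork(nodes=nodes, links=links)


@pytest.fixture
def walk_graph_factory():
    def _make(network):
        return build_mode_graph(network, ModeConfig(mode="walk"))

    return _make
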