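"""Synthetic study region with known ground truth.

Generates a desk-scale stand-in for a national small-area accessibility
study: a planar road network on a perturbed rectangular lattice (with a
road-class hierarchy and one motorway chain closed to walking and
cycling), zones that are lattice cells with populations of 500-1,000,
income-deprivation quintiles with positive spatial autocorrelation
(a smoothed Gaussian field cut into five equal-count groups), a six-fold
urban-rural classification collapsed to urban / small town / rural,
nested local authorities, scheduled bus routes in a weekday inter-peak
window, and facilities placed as an inhomogeneous point process whose
zone intensity is proportional to a known quintile rate ratio — so
downstream models can be checked against the generating truth.

All randomness flows from one seed through per-component substreams;
a fixed configuration therefore reproduces the bundle bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .config import RegionConfig
from .facilities import MetLookup
from .journeys import BusTimetable, Trip
from .network import RoadLink, RoadNetwork, population_weighted_centroid
from .spatial import ZoneAdjacency

#: in-vehicle bus speed on every link, km/h (inter-peak service with stops)
BUS_SPEED_KMH = 20.0


@dataclass
class RegionBundle:
    """Everything one synthetic region comprises, plus the generating truth."""

    network: RoadNetwork
    timetable: BusTimetable
    zones: pd.DataFrame  # zone_id, population, quintile, urc6, stratum, la_id, centroid_x/y
    polygons: dict[Hashable, Polygon]
    adjacency: ZoneAdjacency
    facilities: pd.DataFrame  # facility_id, facility_type, x, y
    truth: dict = field(default_factory=dict)


def _grid_shape(n_zones: int) -> tuple[int, int]:
    nc = int(math.ceil(math.sqrt(n_zones)))
    nr = int(math.ceil(n_zones / nc))
    return nr, nc


def _sample_in_polygon(poly: Polygon, rng: np.random.Generator, k: int) -> list[tuple[float, float]]:
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    while len(pts) < k:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.contains(Point(x, y)):
            pts.append((x, y))
    return pts


def generate_region(config: RegionConfig) -> RegionBundle:
    """Build the full synthetic region for one configuration.

    Deterministic for a fixed seed. Raises if the generated road network
    would leave any zone centroid disconnected.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geom, rng_pop, rng_depr, rng_fac, rng_tt = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    nr, nc = _grid_shape(config.n_zones)
    extent = config.grid_extent_m
    dx, dy = extent / nc, extent / nr

    # perturbed lattice vertices; boundary vertices stay put
    vx = np.empty((nr + 1, nc + 1))
    vy = np.empty((nr + 1, nc + 1))
    jitter = rng_geom.uniform(-0.2, 0.2, size=(nr + 1, nc + 1, 2))
    for i in range(nr + 1):
        for j in range(nc + 1):
            x, y = j * dx, i * dy
            if 0 < i < nr and 0 < j < nc:
                x += jitter[i, j, 0] * dx
                y += jitter[i, j, 1] * dy
            vx[i, j], vy[i, j] = x, y

    # zones: first n_zones cells in row-major order
    cells = [(i, j) for i in range(nr) for j in range(nc)][: config.n_zones]
    zone_ids = [f"Z{k:04d}" for k in range(len(cells))]
    cell_of = dict(zip(zone_ids, cells))
    polygons = {}
    for zid, (i, j) in cell_of.items():
        polygons[zid] = Polygon(
            [
                (vx[i, j], vy[i, j]),
                (vx[i, j + 1], vy[i, j + 1]),
                (vx[i + 1, j + 1], vy[i + 1, j + 1]),
                (vx[i + 1, j], vy[i + 1, j]),
            ]
        )

    # shared-edge adjacency on the lattice
    idx = {c: z for z, c in cell_of.items()}
    neighbours = {z: [] for z in zone_ids}
    for zid, (i, j) in cell_of.items():
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = idx.get((i + di, j + dj))
            if nb is not None:
                neighbours[zid].append(nb)
    adjacency = ZoneAdjacency(zone_ids=zone_ids, neighbours=neighbours)

    network = _build_network(vx, vy, nr, nc)

    # populations in [mean-250, mean+250] (500-1,000 at the default mean)
    lo, hi = config.mean_population - 250, config.mean_population + 250
    populations = rng_pop.integers(int(lo), int(hi) + 1, size=len(zone_ids))

    # household points -> population-weighted centroid per zone
    centroids = {}
    for zid, pop in zip(zone_ids, populations):
        pts = _sample_in_polygon(polygons[zid], rng_pop, 5)
        weights = rng_pop.dirichlet(np.ones(5)) * pop
        centroids[zid] = population_weighted_centroid(zip(pts, weights))

    quintile = _autocorrelated_quintiles(zone_ids, neighbours, rng_depr)
    urc6 = _urban_rural(zone_ids, centroids, polygons, config, extent)
    stratum = {1: "urban", 2: "urban", 3: "small town", 4: "small town",
               5: "rural", 6: "rural"}
    la_id = _local_authorities(zone_ids, centroids, config.n_local_authorities)

    zones = pd.DataFrame(
        {
            "zone_id": zone_ids,
            "population": populations,
            "quintile": [quintile[z] for z in zone_ids],
            "urc6": [urc6[z] for z in zone_ids],
            "stratum": [stratum[urc6[z]] for z in zone_ids],
            "la_id": [la_id[z] for z in zone_ids],
            "centroid_x": [centroids[z][0] for z in zone_ids],
            "centroid_y": [centroids[z][1] for z in zone_ids],
        }
    )

    facilities = _place_facilities(zones, polygons, config, rng_fac)
    timetable = generate_timetable(config, network, rng=rng_tt)

    _check_connected(network, zones)

    return RegionBundle(
        network=network,
        timetable=timetable,
        zones=zones,
        polygons=polygons,
        adjacency=adjacency,
        facilities=facilities,
        truth={
            "seed": config.seed,
            "facility_rate_ratios": dict(config.facility_rate_ratios),
            "facilities_per_zone": config.facilities_per_zone,
        },
    )


def _build_network(vx, vy, nr, nc) -> RoadNetwork:
    """Lattice road network: vertices are junctions, cell edges are links.

    The central column and row are A roads, every third line a B road and
    the rest alternate minor/local; the top boundary chain is a motorway
    (car only). Links are directed both ways.
    """
    nodes = {}
    nid = lambda i, j: i * (nc + 1) + j
    for i in range(nr + 1):
        for j in range(nc + 1):
            nodes[nid(i, j)] = (float(vx[i, j]), float(vy[i, j]))

    def road_class(i0, j0, i1, j1):
        if i0 == i1 == nr:  # top chain (row-major: highest i is the far edge)
            return "motorway"
        if i0 == i1:  # horizontal link on row i0
            if i0 == nr // 2:
                return "A"
            if i0 % 3 == 0:
                return "B"
            return "minor" if i0 % 2 else "local"
        # vertical link in column j0
        if j0 == nc // 2:
            return "A"
        if j0 % 3 == 0:
            return "B"
        return "minor" if j0 % 2 else "local"

    links = []
    for i in range(nr + 1):
        for j in range(nc + 1):
            for i2, j2 in ((i, j + 1), (i + 1, j)):
                if i2 > nr or j2 > nc:
                    continue
                rc = road_class(i, j, i2, j2)
                length = math.hypot(vx[i2, j2] - vx[i, j], vy[i2, j2] - vy[i, j])
                active = rc != "motorway"
                for u, v in ((nid(i, j), nid(i2, j2)), (nid(i2, j2), nid(i, j))):
                    links.append(
                        RoadLink(u=u, v=v, length_m=length, road_class=rc,
                                 walk=active, cycle=active, car=True)
                    )
    return RoadNetwork(nodes=nodes, links=links)


def _autocorrelated_quintiles(zone_ids, neighbours, rng) -> dict:
    """Smooth an i.i.d. Gaussian field over the adjacency graph, then cut
    into five equal-count quintiles (guaranteeing all five are non-empty
    once there are at least five zones)."""
    x = rng.standard_normal(len(zone_ids))
    index = {z: i for i, z in enumerate(zone_ids)}
    for _ in range(3):
        smoothed = x.copy()
        for z, ns in neighbours.items():
            if ns:
                smoothed[index[z]] = 0.5 * x[index[z]] + 0.5 * np.mean(
                    [x[index[n]] for n in ns]
                )
        x = smoothed
    order = np.argsort(x, kind="stable")
    q = np.empty(len(zone_ids), dtype=int)
    # ranks 0..n-1 cut into 5 blocks: most affluent (lowest field) = Q1
    q[order] = 1 + (np.arange(len(zone_ids)) * 5) // len(zone_ids)
    return {z: int(q[index[z]]) for z in zone_ids}


def _urban_rural(zone_ids, centroids, polygons, config, extent) -> dict:
    """Categories 1-6 by distance to the urban core (the network's densest
    central cluster), split to match the configured strata fractions."""
    core = (extent / 2.0, extent / 2.0)
    dist = {
        z: math.hypot(centroids[z][0] - core[0], centroids[z][1] - core[1])
        for z in zone_ids
    }
    ranked = sorted(zone_ids, key=lambda z: (dist[z], z))
    n = len(zone_ids)
    n_urban = int(round(config.urban_fraction * n))
    n_small = int(round(config.smalltown_fraction * n))
    out = {}
    for k, z in enumerate(ranked):
        if k < n_urban:
            out[z] = 1 if k < n_urban // 2 else 2
        elif k < n_urban + n_small:
            out[z] = 3 if (k - n_urban) < n_small // 2 else 4
        else:
            out[z] = 5 if (k - n_urban - n_small) < (n - n_urban - n_small) // 2 else 6
    return out


def _local_authorities(zone_ids, centroids, n_las) -> dict:
    """Contiguous vertical bands with near-equal zone counts."""
    ranked = sorted(zone_ids, key=lambda z: (centroids[z][0], z))
    out = {}
    for k, z in enumerate(ranked):
        out[z] = f"LA{(k * n_las) // len(zone_ids) + 1}"
    return out


def _place_facilities(zones, polygons, config, rng) -> pd.DataFrame:
    """Inhomogeneous point process: the expected count in a zone of
    quintile q is proportional to facility_rate_ratios[q], normalised so
    the region-wide mean per zone equals ``facilities_per_zone``."""
    rr = config.facility_rate_ratios
    weights = zones["quintile"].map(rr).to_numpy(float)
    lam = config.facilities_per_zone * weights * len(zones) / weights.sum()
    types = MetLookup.default().types
    rows = []
    for zid, li in zip(zones["zone_id"], lam):
        k = rng.poisson(li)
        if k == 0:
            continue
        pts = _sample_in_polygon(polygons[zid], rng, k)
        for x, y in pts:
            rows.append(
                {
                    "facility_id": f"F{len(rows):05d}",
                    "facility_type": types[rng.integers(len(types))],
                    "x": x,
                    "y": y,
                }
            )
    return pd.DataFrame(rows, columns=["facility_id", "facility_type", "x", "y"])


def generate_timetable(
    config: RegionConfig,
    network: RoadNetwork,
    rng: np.random.Generator | None = None,
) -> BusTimetable:
    """Scheduled bus routes as stop sequences along the road graph.

    Each route follows a shortest road path between two sampled junctions,
    serving every second junction as a stop; trips depart on a fixed
    headway and only run if they finish inside the service window.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    import networkx as nx

    g = nx.Graph()
    for lk in network.links:
        if lk.road_class != "motorway":
            g.add_edge(lk.u, lk.v, length=lk.length_m)
    node_ids = sorted(g.nodes)
    coords = network.nodes

    stops: dict[str, Hashable] = {}
    stop_of_node: dict[Hashable, str] = {}
    routes: dict[str, list[str]] = {}
    trips: list[Trip] = []
    w0, w1 = config.service_window

    for r in range(config.bus_routes):
        for _ in range(50):  # draw endpoints until the route is long enough
            a, b = rng.choice(len(node_ids), size=2, replace=False)
            u, v = node_ids[a], node_ids[b]
            if math.hypot(
                coords[u][0] - coords[v][0], coords[u][1] - coords[v][1]
            ) > 0.3 * config.grid_extent_m:
                break
        path = nx.shortest_path(g, u, v, weight="length")
        stop_nodes = path[::2]
        if stop_nodes[-1] != path[-1]:
            stop_nodes = stop_nodes + [path[-1]]
        seq = []
        for n in stop_nodes:
            if n not in stop_of_node:
                sid = f"S{len(stops):03d}"
                stops[sid] = n
                stop_of_node[n] = sid
            seq.append(stop_of_node[n])
        rid = f"R{r:02d}"
        routes[rid] = seq

        # cumulative in-vehicle minutes between consecutive stops
        offsets = [0.0]
        for n1, n2 in zip(stop_nodes, stop_nodes[1:]):
            d = nx.shortest_path_length(g, n1, n2, weight="length")
            offsets.append(offsets[-1] + (d / 1000.0) / BUS_SPEED_KMH * 60.0)
        k = 0
        dep = w0
        while dep < w1:
            if dep + offsets[-1] < w1:
                trips.append(
                    Trip(
                        trip_id=f"{rid}T{k:02d}",
                        route_id=rid,
                        stop_ids=list(seq),
                        departures_min=[dep + o for o in offsets],
                    )
                )
            dep += config.headway_min
            k += 1
    return BusTimetable(stops=stops, routes=routes, trips=trips)


def _check_connected(network: RoadNetwork, zones: pd.DataFrame) -> None:
    import networkx as nx

    for mode in ("walk", "car"):
        g = nx.Graph()
        for lk in network.links:
            if lk.permits(mode):
                g.add_edge(lk.u, lk.v)
        if g.number_of_nodes() == 0 or not nx.is_connected(g):
            raise ValueError(f"generated {mode} network is disconnected")
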