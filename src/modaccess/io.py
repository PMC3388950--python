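"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: GeoJSON for geometry (planar metre coordinates),
CSV attribute tables, and a GTFS-subset timetable (stops.txt, routes.txt,
trips.txt, stop_times.txt with HH:MM:SS clock times). Writers emit sorted
keys and stable column orders so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Hashable

import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .config import format_clock, parse_clock
from .journeys import BusTimetable, Trip
from .network import RoadLink, RoadNetwork
from .spatial import ZoneAdjacency


def _dump_geojson(features: list[dict], path) -> None:
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")


# ---------------------------------------------------------------------------
# road network


def write_network_geojson(network: RoadNetwork, path) -> None:
    """Directed links as LineStrings with properties
    {u, v, length_m, road_class, walk, cycle, car}."""
    feats = []
    for lk in network.links:
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(network.nodes[lk.u]), list(network.nodes[lk.v])],
                },
                "properties": {
                    "u": lk.u,
                    "v": lk.v,
                    "length_m": round(lk.length_m, 6),
                    "road_class": lk.road_class,
                    "walk": lk.walk,
                    "cycle": lk.cycle,
                    "car": lk.car,
                },
            }
        )
    _dump_geojson(feats, path)


def read_network_geojson(path) -> RoadNetwork:
    fc = json.loads(Path(path).read_text())
    nodes: dict[Hashable, tuple[float, float]] = {}
    links = []
    for feat in fc["features"]:
        props = feat["properties"]
        (x0, y0), (x1, y1) = feat["geometry"]["coordinates"]
        nodes[props["u"]] = (x0, y0)
        nodes[props["v"]] = (x1, y1)
        links.append(
            RoadLink(
                u=props["u"], v=props["v"], length_m=props["length_m"],
                road_class=props["road_class"], walk=props["walk"],
                cycle=props["cycle"], car=props["car"],
            )
        )
    return RoadNetwork(nodes=nodes, links=links)


# ---------------------------------------------------------------------------
# zones


def write_zones(zones: pd.DataFrame, polygons: dict[Hashable, Polygon], out_dir) -> None:
    out = Path(out_dir)
    feats = []
    for zid in zones["zone_id"]:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(polygons[zid]),
                "properties": {"zone_id": zid},
            }
        )
    _dump_geojson(feats, out / "zones.geojson")
    zones.to_csv(out / "zones.csv", index=False)


def read_zones(out_dir) -> tuple[pd.DataFrame, dict[Hashable, Polygon]]:
    out = Path(out_dir)
    zones = pd.read_csv(out / "zones.csv")
    fc = json.loads((out / "zones.geojson").read_text())
    polygons = {
        f["properties"]["zone_id"]: shape(f["geometry"]) for f in fc["features"]
    }
    return zones, polygons


def write_adjacency(adjacency: ZoneAdjacency, path) -> None:
    rows = [
        {"zone_id": z, "neighbour_id": n}
        for z in adjacency.zone_ids
        for n in sorted(adjacency.neighbours.get(z, []))
    ]
    pd.DataFrame(rows, columns=["zone_id", "neighbour_id"]).to_csv(path, index=False)


def read_adjacency(path, zone_ids=None) -> ZoneAdjacency:
    df = pd.read_csv(path)
    if zone_ids is None:
        zone_ids = sorted(set(df["zone_id"]) | set(df["neighbour_id"]))
    neighbours = {z: [] for z in zone_ids}
    for z, n in zip(df["zone_id"], df["neighbour_id"]):
        neighbours[z].append(n)
    return ZoneAdjacency(zone_ids=list(zone_ids), neighbours=neighbours)


# ---------------------------------------------------------------------------
# GTFS subset


def write_gtfs(timetable: BusTimetable, network: RoadNetwork, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stops = pd.DataFrame(
        [
            {
                "stop_id": sid,
                "node_id": node,
                "stop_x": network.nodes[node][0],
                "stop_y": network.nodes[node][1],
            }
            for sid, node in timetable.stops.items()
        ]
    )
    stops.to_csv(out / "stops.txt", index=False)
    pd.DataFrame(
        [{"route_id": rid} for rid in timetable.routes]
    ).to_csv(out / "routes.txt", index=False)
    pd.DataFrame(
        [{"trip_id": t.trip_id, "route_id": t.route_id} for t in timetable.trips]
    ).to_csv(out / "trips.txt", index=False)
    st_rows = []
    for t in timetable.trips:
        for k, (sid, dep) in enumerate(zip(t.stop_ids, t.departures_min)):
            clock = format_clock(dep)
            st_rows.append(
                {
                    "trip_id": t.trip_id,
                    "stop_id": sid,
                    "stop_sequence": k,
                    "arrival_time": clock,
                    "departure_time": clock,
                }
            )
    pd.DataFrame(st_rows).to_csv(out / "stop_times.txt", index=False)


def read_gtfs(gtfs_dir) -> BusTimetable:
    d = Path(gtfs_dir)
    stops_df = pd.read_csv(d / "stops.txt")
    stops = dict(zip(stops_df["stop_id"], stops_df["node_id"]))
    trips_df = pd.read_csv(d / "trips.txt")
    st = pd.read_csv(d / "stop_times.txt")
    trips = []
    routes: dict[str, list[str]] = {}
    for trip_id, grp in st.groupby("trip_id", sort=True):
        grp = grp.sort_values("stop_sequence")
        route_id = trips_df.loc[trips_df["trip_id"] == trip_id, "route_id"].iloc[0]
        seq = list(grp["stop_id"])
        routes.setdefault(route_id, seq)
        trips.append(
            Trip(
                trip_id=trip_id,
                route_id=route_id,
                stop_ids=seq,
                departures_min=[parse_clock(t) for t in grp["departure_time"]],
            )
        )
    return BusTimetable(stops=stops, routes=routes, trips=trips)
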