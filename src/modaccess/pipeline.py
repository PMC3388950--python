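"""End-to-end orchestration: simulate -> classify -> network -> times ->
counts -> model.

Each stage writes plain-text artifacts into the output directory and
records a fingerprint of its configuration (chained to its upstream
stage), so a rerun skips stages whose inputs are unchanged — changing
only an analysis threshold reuses the routing matrices. The manifest
lists every artifact with its SHA-256 hash, the seed, and stage timings;
under a fixed seed the artifact hashes are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .access import accessibility_table, quintile_summary
from .config import PipelineConfig
from .facilities import MetLookup, classify_facilities, drop_light
from .journeys import travel_time_matrix
from .models import stratified_analysis
from .network import build_mode_graph, connect_point
from .synthetic import generate_region

log = logging.getLogger("modaccess")

STAGES = ("simulate", "classify", "network", "times", "counts", "model")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fingerprint(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


class _Stage:
    def __init__(self, name: str, out: Path, outputs: list[str], fp: str):
        self.name = name
        self.out = out
        self.outputs = [out / o for o in outputs]
        self.fp = fp
        self.marker = out / f".stage_{name}.json"

    def fresh(self) -> bool:
        if not all(p.exists() for p in self.outputs):
            return False
        if not self.marker.exists():
            return False
        try:
            return json.loads(self.marker.read_text())["fingerprint"] == self.fp
        except Exception:
            return False

    def done(self) -> None:
        self.marker.write_text(json.dumps({"fingerprint": self.fp}))


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Run (or resume) every stage; returns the manifest.

    A stage failure raises with the stage named; completed stages keep
    their outputs on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtfs_dir = out / "gtfs"
    manifest: dict = {
        "seed": config.region.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    cfg = config.to_dict()
    fps: dict[str, str] = {}
    fps["simulate"] = _fingerprint(cfg["region"])
    fps["classify"] = _fingerprint([fps["simulate"]])
    fps["network"] = _fingerprint([fps["simulate"], cfg["walk"], cfg["cycle"], cfg["car"]])
    fps["times"] = _fingerprint([fps["network"], fps["classify"], cfg["bus"]])
    fps["counts"] = _fingerprint([fps["times"], cfg["analysis"]])
    fps["model"] = _fingerprint([fps["counts"], cfg["model"]])

    stage_outputs = {
        "simulate": ["network.geojson", "zones.geojson", "zones.csv", "facilities.csv",
                     "adjacency.csv", "gtfs/stops.txt", "gtfs/routes.txt",
                     "gtfs/trips.txt", "gtfs/stop_times.txt"],
        "classify": ["facilities_classified.csv", "facility_rejects.csv"],
        "network": ["modegraph_walk.csv", "modegraph_cycle.csv", "modegraph_car.csv"],
        "times": ["times.csv"],
        "counts": ["access_table.csv", "quintile_summary.csv"],
        "model": ["model_results.csv"],
    }

    runners = {
        "simulate": lambda: _stage_simulate(config, out, gtfs_dir),
        "classify": lambda: _stage_classify(out),
        "network": lambda: _stage_network(config, out),
        "times": lambda: _stage_times(config, out, gtfs_dir),
        "counts": lambda: _stage_counts(config, out),
        "model": lambda: _stage_model(config, out),
    }

    for name in STAGES:
        stage = _Stage(name, out, stage_outputs[name], fps[name])
        t0 = time.perf_counter()
        if stage.fresh() and not force:
            log.info("stage %s: cached, skipping", name)
            cached = True
        else:
            log.info("stage %s: running", name)
            try:
                runners[name]()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stage.done()
            cached = False
        manifest["stages"][name] = {
            "cached": cached,
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in stage.outputs},
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, out: Path, gtfs_dir: Path) -> None:
    bundle = generate_region(config.region)
    mio.write_network_geojson(bundle.network, out / "network.geojson")
    mio.write_zones(bundle.zones, bundle.polygons, out)
    bundle.facilities.to_csv(out / "facilities.csv", index=False)
    mio.write_adjacency(bundle.adjacency, out / "adjacency.csv")
    mio.write_gtfs(bundle.timetable, bundle.network, gtfs_dir)


def _stage_classify(out: Path) -> None:
    raw = pd.read_csv(out / "facilities.csv")
    result = classify_facilities(raw, MetLookup.default())
    result.to_frame().to_csv(out / "facilities_classified.csv", index=False)
    pd.DataFrame(result.rejects, columns=["facility_type", "x", "y", "reason"]).to_csv(
        out / "facility_rejects.csv", index=False
    )


def _load_graphs(config: PipelineConfig, out: Path):
    network = mio.read_network_geojson(out / "network.geojson")
    zones = pd.read_csv(out / "zones.csv")
    fac = pd.read_csv(out / "facilities_classified.csv")
    fac = fac[fac["intensity"] != "light"] if not config.analysis.include_light else fac
    graphs = {}
    zone_nodes: dict[str, dict] = {}
    fac_nodes: dict[str, dict] = {}
    for mode, mcfg in (("walk", config.walk), ("cycle", config.cycle), ("car", config.car)):
        g = build_mode_graph(network, mcfg)
        zn, fn = {}, {}
        for zid, x, y in zip(zones["zone_id"], zones["centroid_x"], zones["centroid_y"]):
            pid = f"zone:{zid}"
            connect_point(g, pid, (x, y))
            zn[zid] = pid
        for fid, x, y in zip(fac["facility_id"], fac["x"], fac["y"]):
            pid = f"fac:{fid}"
            connect_point(g, pid, (x, y))
            fn[fid] = pid
        graphs[mode] = g
        zone_nodes[mode] = zn
        fac_nodes[mode] = fn
    return network, zones, fac, graphs, zone_nodes, fac_nodes


def _stage_network(config: PipelineConfig, out: Path) -> None:
    network = mio.read_network_geojson(out / "network.geojson")
    for mode, mcfg in (("walk", config.walk), ("cycle", config.cycle), ("car", config.car)):
        g = build_mode_graph(network, mcfg)
        rows = [
            {"u": u, "v": v, "length_m": a["length_m"], "time_min": a["time_min"],
             "road_class": a["road_class"]}
            for u, v, a in g.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(out / f"modegraph_{mode}.csv", index=False)


def _stage_times(config: PipelineConfig, out: Path, gtfs_dir: Path) -> None:
    _, zones, fac, graphs, zone_nodes, fac_nodes = _load_graphs(config, out)
    timetable = mio.read_gtfs(gtfs_dir)
    frames = []
    for mode in ("walk", "cycle", "car"):
        m = travel_time_matrix(
            mode, graphs[mode], list(zones["zone_id"]), list(fac["facility_id"]),
            zone_nodes[mode], fac_nodes[mode],
        )
        frames.append(m.to_frame())
    m_bus = travel_time_matrix(
        "bus", graphs["walk"], list(zones["zone_id"]), list(fac["facility_id"]),
        zone_nodes["walk"], fac_nodes["walk"],
        timetable=timetable, bus_config=config.bus,
    )
    frames.append(m_bus.to_frame())
    pd.concat(frames, ignore_index=True).to_csv(out / "times.csv", index=False)


def _stage_counts(config: PipelineConfig, out: Path) -> None:
    from .facilities import Facility
    from .journeys import TravelTimeMatrix

    times = pd.read_csv(out / "times.csv")
    zones = pd.read_csv(out / "zones.csv")
    fac = pd.read_csv(out / "facilities_classified.csv")
    facilities = [
        Facility(r.facility_id, r.facility_type, r.x, r.y, r.met, r.intensity)
        for r in fac.itertuples(index=False)
    ]
    matrices = {
        mode: TravelTimeMatrix.from_frame(times, mode)
        for mode in sorted(times["mode"].unique())
    }
    table = accessibility_table(matrices, facilities, zones, config.analysis)
    table.to_csv(out / "access_table.csv", index=False)
    quintile_summary(table, zones).to_csv(out / "quintile_summary.csv", index=False)


def _stage_model(config: PipelineConfig, out: Path) -> None:
    counts = pd.read_csv(out / "access_table.csv")
    zones = pd.read_csv(out / "zones.csv")
    adjacency = mio.read_adjacency(out / "adjacency.csv", zone_ids=list(zones["zone_id"]))
    tidy, _ = stratified_analysis(
        counts, zones, adjacency,
        conf_level=config.model.conf_level,
        n_permutations=config.model.n_permutations,
        seed=config.region.seed,
        quad_points=config.model.quad_points,
        modes=list(config.model.modes),
    )
    tidy.to_csv(out / "model_results.csv", index=False)
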