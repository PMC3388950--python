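import numpy as np
import pytest

from conftest import make_network, random_geometric_network
from helpers_oracles import enumerate_bus_minutes, enumerate_car_minutes, enumerate_walk_minutes
from modaccess.config import BusConfig, ModeConfig
from modaccess.journeys import (
    BusRouter,
    BusTimetable,
    TravelTimeMatrix,
    Trip,
    bus_time,
    car_time,
    travel_time_matrix,
    walk_cycle_time,
)
from modaccess.network import build_mode_graph, connect_point


def build_walk(net):
    return build_mode_graph(net, ModeConfig(mode="walk"))


class TestWalkCycle:
    def test_parallel_routes_shorter_wins(self):
        """1,000 m vs 1,200 m alternatives on foot: 12.0 min."""
        nodes = {0: (0.0, 0.0), 1: (500.0, 100.0), 2: (1000.0, 0.0), 3: (500.0, -300.0)}
        net = make_network(nodes, [(0, 1, 500.0), (1, 2, 500.0), (0, 3, 600.0), (3, 2, 600.0)])
        g = build_walk(net)
        assert walk_cycle_time(g, 0, 2) == pytest.approx(12.0)

    def test_origin_equals_dest(self):
        nodes = {0: (0.0, 0.0), 1: (10.0, 0.0)}
        g = build_walk(make_network(nodes, [(0, 1, 10.0)]))
        assert walk_cycle_time(g, 0, 0) == 0.0

    def test_disconnected_pair_is_unreachable_not_an_exception(self):
        nodes = {0: (0.0, 0.0), 1: (10.0, 0.0), 2: (99.0, 99.0), 3: (99.0, 0.0)}
        g = build_walk(make_network(nodes, [(0, 1, 10.0), (2, 3, 99.0)]))
        assert walk_cycle_time(g, 0, 2) == float("inf")

    def test_shortest_by_distance_not_by_time(self):
        """Walk and cycle use the same (distance-optimal) route, so times
        sit in the exact 14:5 ratio."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_geometric_network(rng)
            gw = build_walk(net)
            gc = build_mode_graph(net, ModeConfig(mode="cycle"))
            n = len(net.nodes)
            tw = walk_cycle_time(gw, 0, n - 1)
            tc = walk_cycle_time(gc, 0, n - 1)
            assert tc == pytest.approx(tw * 5.0 / 14.0)


class TestCar:
    def test_single_link_free_flow(self):
        """1 km at 60 km/h with no junctions: 1.0 min."""
        nodes = {0: (0.0, 0.0), 1: (1000.0, 0.0)}
        net = make_network(nodes, [(0, 1, 1000.0)], road_class="A")
        cfg = ModeConfig(mode="car", freeflow_kmh={"A": 60.0})
        g = build_mode_graph(net, cfg)
        assert car_time(g, 0, 1, cfg) == pytest.approx(1.0)

    def test_turnfree_detour_can_beat_shorter_turning_route(self):
        """With heavy turn penalties the fastest route avoids the turns."""
        # route A: 0->1->2->3 (two sharp turns); route B: 0->4->3 (straight, longer)
        nodes = {
            0: (0.0, 0.0), 1: (400.0, 0.0), 2: (400.0, 400.0), 3: (800.0, 400.0),
            4: (450.0, 220.0),
        }
        net = make_network(
            nodes,
            [(0, 1, 400.0), (1, 2, 400.0), (2, 3, 400.0), (0, 4, 500.0), (4, 3, 400.0)],
            road_class="local",
        )
        cfg = ModeConfig(
            mode="car",
            freeflow_kmh={"local": 30.0},
            turn_penalties_s={"left": 60.0, "right": 90.0},
            straight_threshold_deg=30.0,
        )
        g = build_mode_graph(net, cfg)
        t = car_time(g, 0, 3, cfg)
        # route B: 900 m @ 30 km/h = 1.8 min, bearing changes under 30 deg
        assert t == pytest.approx(900.0 / 1000.0 / 30.0 * 60.0)
        # route A would be 1200 m = 2.4 min plus 2 penalties
        assert t < 2.4

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        cfg = ModeConfig(mode="car")
        for _ in range(30):
            net = random_geometric_network(rng)
            g = build_mode_graph(net, cfg)
            n = len(net.nodes)
            o, d = 0, n - 1
            assert car_time(g, o, d, cfg) == pytest.approx(
                enumerate_car_minutes(g, o, d, cfg), abs=1e-9
            )


def toy_bus_world(n_stops=4, spacing=1000.0, headway=15.0, inveh=4.0,
                  window=(600.0, 960.0), n_trips=None):
    """Stops in a line along a walkable road; one route end to end."""
    nodes = {i: (i * spacing, 0.0) for i in range(n_stops)}
    edges = [(i, i + 1, spacing) for i in range(n_stops - 1)]
    net = make_network(nodes, edges)
    g = build_walk(net)
    stops = {f"S{i}": i for i in range(n_stops)}
    seq = [f"S{i}" for i in range(n_stops)]
    trips = []
    k = 0
    dep = window[0]
    while dep + inveh * (n_stops - 1) < window[1] and (n_trips is None or k < n_trips):
        trips.append(
            Trip(f"T{k:02d}", "R0", seq, [dep + inveh * i for i in range(n_stops)])
        )
        dep += headway
        k += 1
    tt = BusTimetable(stops=stops, routes={"R0": seq}, trips=trips)
    return net, g, tt


class TestBus:
    def test_simple_ride(self):
        """Timed arrival at the first stop: total = access + in-vehicle + egress."""
        net, g, tt = toy_bus_world()
        cfg = BusConfig()
        t = bus_time(tt, g, 0, 3, cfg)
        assert t == pytest.approx(3 * 4.0)  # board at origin node, ride 3 legs

    def test_walk_only_never_substitutes(self):
        """Adjacent stops an easy walk apart still require a boarding."""
        net, g, tt = toy_bus_world(n_trips=1)
        cfg = BusConfig()
        t = bus_time(tt, g, 0, 1, cfg)
        assert t == pytest.approx(4.0)  # one in-vehicle leg, not the 12-min walk

    def test_transfer_limit_enforced(self):
        """Three boardings (two transfers) is allowed; four is not.

        Stops sit 3 km apart (a 36-min walk), so intermediate access,
        egress and walk-ahead interchanges are all impossible: the only
        way from node 0 to node 6 is the chain of three single-trip
        routes meeting with 4-minute connections.
        """
        n = 7
        nodes = {i: (i * 3000.0, 0.0) for i in range(n)}
        net = make_network(nodes, [(i, i + 1, 3000.0) for i in range(n - 1)])
        g = build_walk(net)
        stops = {f"S{i}": i for i in range(n)}
        segs = {
            "R0": (["S0", "S1", "S2"], [600.0, 604.0, 608.0]),
            "R1": (["S2", "S3", "S4"], [612.0, 616.0, 620.0]),
            "R2": (["S4", "S5", "S6"], [624.0, 628.0, 632.0]),
        }
        timetable = BusTimetable(
            stops=stops,
            routes={rid: seq for rid, (seq, _) in segs.items()},
            trips=[Trip(f"{rid}T0", rid, seq, times) for rid, (seq, times) in segs.items()],
        )
        t = bus_time(timetable, g, 0, 6, BusConfig(max_transfers=2))
        assert t == pytest.approx(32.0)  # 600 -> 632, zero access/egress
        assert bus_time(timetable, g, 0, 6, BusConfig(max_transfers=1)) == float("inf")

    def test_wait_cap_excludes_long_interchanges(self):
        """An 8-minute connection violates the 5-minute wait cap.

        Stops are 2 km apart so the connection cannot be dodged by
        walking ahead to a later stop of the onward trip.
        """
        nodes = {i: (i * 2000.0, 0.0) for i in range(5)}
        net = make_network(nodes, [(i, i + 1, 2000.0) for i in range(4)])
        g = build_walk(net)
        stops = {f"S{i}": i for i in range(5)}
        t1 = Trip("A", "R1", ["S0", "S1", "S2"], [600.0, 604.0, 608.0])
        t2 = Trip("B", "R2", ["S2", "S3", "S4"], [616.0, 620.0, 624.0])  # 8-min wait
        tt = BusTimetable(stops=stops, routes={"R1": t1.stop_ids, "R2": t2.stop_ids},
                          trips=[t1, t2])
        assert bus_time(tt, g, 0, 4, BusConfig(max_wait_min=5.0)) == float("inf")
        assert np.isfinite(bus_time(tt, g, 0, 4, BusConfig(max_wait_min=10.0)))

    def test_monotone_in_relaxed_constraints(self):
        """Feasible itineraries only grow as any cap is relaxed."""
        net, g, tt = toy_bus_world(n_stops=6, spacing=1500.0)
        base = BusConfig()
        t0 = bus_time(tt, g, 0, 5, base)
        for relaxed in (
            BusConfig(max_transfers=5),
            BusConfig(max_access_egress_walk_min=60.0),
            BusConfig(max_wait_min=30.0),
        ):
            assert bus_time(tt, g, 0, 5, relaxed) <= t0

    def test_matches_itinerary_enumeration(self):
        rng = np.random.default_rng(3)
        cfg = BusConfig()
        for _ in range(15):
            n_stops = int(rng.integers(3, 6))
            net, g, tt = toy_bus_world(
                n_stops=n_stops,
                spacing=float(rng.integers(800, 2000)),
                headway=float(rng.integers(10, 30)),
                inveh=float(rng.integers(2, 6)),
                n_trips=int(rng.integers(2, 5)),
            )
            o = int(rng.integers(0, n_stops))
            d = int(rng.integers(0, n_stops))
            assert bus_time(tt, g, o, d, cfg) == pytest.approx(
                enumerate_bus_minutes(tt, g, o, d, cfg), abs=1e-9
            )


class TestMatrix:
    def build_region_like(self, rng):
        net = random_geometric_network(rng, n_nodes=8)
        g = build_walk(net)
        zone_pts = {f"z{i}": tuple(rng.uniform(0, 2000, 2)) for i in range(3)}
        fac_pts = {f"f{i}": tuple(rng.uniform(0, 2000, 2)) for i in range(4)}
        zn, fn = {}, {}
        for zid, pt in zone_pts.items():
            pid = f"zone:{zid}"
            connect_point(g, pid, pt)
            zn[zid] = pid
        for fid, pt in fac_pts.items():
            pid = f"fac:{fid}"
            connect_point(g, pid, pt)
            fn[fid] = pid
        return g, zn, fn

    def test_shape_and_self_consistency_with_per_pair_calls(self):
        rng = np.random.default_rng(8)
        g, zn, fn = self.build_region_like(rng)
        m = travel_time_matrix("walk", g, list(zn), list(fn), zn, fn)
        assert m.minutes.shape == (3, 4)
        for i, z in enumerate(m.origins):
            for j, f in enumerate(m.destinations):
                assert m.minutes[i, j] == pytest.approx(
                    walk_cycle_time(g, zn[z], fn[f]), abs=1e-9
                )

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        g, zn, fn = self.build_region_like(rng)
        fids = list(fn)
        m1 = travel_time_matrix("walk", g, list(zn), fids, zn, fn)
        m2 = travel_time_matrix("walk", g, list(zn), fids[::-1], zn, fn)
        assert np.allclose(m1.minutes, m2.minutes[:, ::-1])

    def test_long_format_roundtrip(self):
        rng = np.random.default_rng(8)
        g, zn, fn = self.build_region_like(rng)
        m = travel_time_matrix("walk", g, list(zn), list(fn), zn, fn)
        df = m.to_frame()
        assert len(df) == 12
        back = TravelTimeMatrix.from_frame(df, "walk")
        # from_frame sorts ids; compare via lookups
        for i, z in enumerate(back.origins):
            for j, f in enumerate(back.destinations):
                orig = m.minutes[m.origins.index(z), m.destinations.index(f)]
                assert back.minutes[i, j] == pytest.approx(orig, abs=1e-9)
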