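"""Independent brute-force oracles for routing: exhaustive enumeration on
tiny instances, kept deliberately separate from the search code they check."""

import networkx as nx

from modaccess.network import apply_turn_penalties


def enumerate_walk_minutes(graph, origin, dest):
    """Minimum-distance time by enumerating every simple path."""
    g = graph.graph
    if origin == dest:
        return 0.0
    best = float("inf")
    if origin not in g or dest not in g:
        return best
    for path in nx.all_simple_paths(g, origin, dest):
        L = sum(g[u][v]["length_m"] for u, v in zip(path, path[1:]))
        best = min(best, L)
    if best == float("inf"):
        return best
    return (best / 1000.0) / graph.config.speed_kmh * 60.0


def enumerate_car_minutes(graph, origin, dest, config):
    """Fastest time over every simple path, turn penalties included."""
    g = graph.graph
    if origin == dest:
        return 0.0
    best = float("inf")
    if origin not in g or dest not in g:
        return best
    for path in nx.all_simple_paths(g, origin, dest):
        t = sum(g[u][v]["time_min"] for u, v in zip(path, path[1:]))
        t += apply_turn_penalties(path, graph, config) / 60.0
        best = min(best, t)
    return best


def enumerate_bus_minutes(timetable, walk_graph, origin, dest, config):
    """Minimum feasible bus journey by recursive itinerary enumeration.

    Mirrors the journey rules — at most ``max_transfers`` transfers, access
    and egress walks capped, every interchange wait capped, first wait zero
    (timed arrival), at least one ride link — but by explicit enumeration
    of (boarding event, alighting position) sequences.
    """
    if origin == dest:
        return 0.0
    walk_from_origin = nx.single_source_dijkstra_path_length(
        walk_graph.graph, origin, weight="time_min"
    )
    walk_to_dest = nx.single_source_dijkstra_path_length(
        walk_graph.graph.reverse(copy=False), dest, weight="time_min"
    )
    stop_walks = {
        sid: nx.single_source_dijkstra_path_length(
            walk_graph.graph, node, weight="time_min"
        )
        for sid, node in timetable.stops.items()
    }
    w0, w1 = config.service_window
    trips = [t for t in timetable.trips if w0 <= t.departures_min[0] < w1]
    best = [float("inf")]

    def extend(trip, board_pos, boardings, elapsed_at_board, board_clock):
        tr = trip
        for alight in range(board_pos + 1, len(tr.stop_ids)):
            clock = tr.departures_min[alight]
            elapsed = elapsed_at_board + (clock - board_clock)
            stop = tr.stop_ids[alight]
            egress = walk_to_dest.get(timetable.stops[stop])
            if egress is not None and egress <= config.max_access_egress_walk_min:
                best[0] = min(best[0], elapsed + egress)
            if boardings <= config.max_transfers:
                walks = stop_walks[stop]
                for t2 in trips:
                    for pos2, s2 in enumerate(t2.stop_ids[:-1]):
                        w = walks.get(timetable.stops[s2])
                        if w is None:
                            continue
                        dep2 = t2.departures_min[pos2]
                        wait = dep2 - (clock + w)
                        if 0 <= wait <= config.max_wait_min:
                            extend(
                                t2, pos2, boardings + 1,
                                elapsed + w + wait, dep2,
                            )

    for t in trips:
        for pos, s in enumerate(t.stop_ids[:-1]):
            a = walk_from_origin.get(timetable.stops[s])
            if a is None or a > config.max_access_egress_walk_min:
                continue
            extend(t, pos, 1, a, t.departures_min[pos])
    return best[0]
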