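"""Network structure, geometry, and feature derivation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hyrim.network import (
    GeometryError,
    Junction,
    NetworkStructureError,
    RiverNetwork,
    Segment,
    StationRecord,
    direction_relation,
    euclidean_distance,
    hydrologic_distance,
    pairwise_features,
    read_network_csv,
    read_stations_csv,
    sinuosity_index,
    strahler_orders,
    travel_time,
    write_network_csv,
    write_stations_csv,
)
from hyrim.synth import SynthConfig, generate_network


# ---------------------------------------------------------------------- #
# Strahler order


def test_strahler_y_network(y_network):
    assert strahler_orders(y_network) == {"A": 1, "B": 1, "C": 2, "D": 2}


def _strahler_bruteforce(g, node):
    preds = list(g.predecessors(node))
    if not preds:
        return 1
    vals = [_strahler_bruteforce(g, p) for p in preds]
    top = max(vals)
    return top + 1 if vals.count(top) >= 2 else top


@pytest.mark.parametrize("seed", range(10))
def test_strahler_matches_recursive_oracle(seed):
    net = generate_network(SynthConfig(n_stations=15, seed=seed))
    got = strahler_orders(net)
    for node in net.graph.nodes:
        assert got[node] == _strahler_bruteforce(net.graph, node)


def test_station_order_input_overrides_derived(y_network):
    y_network.stations["SA"].strahler_order = 3
    assert y_network.station_order("SA") == 3
    assert y_network.station_order("SB") == 1


# ---------------------------------------------------------------------- #
# distances, sinuosity, travel time


def test_hydrologic_distance_values_and_symmetry(y_network):
    assert hydrologic_distance(y_network, "SA", "SD") == pytest.approx(1000.0)
    assert hydrologic_distance(y_network, "SA", "SB") == pytest.approx(1100.0)
    assert hydrologic_distance(y_network, "SD", "SA") == pytest.approx(
        hydrologic_distance(y_network, "SA", "SD")
    )


def test_hydrologic_distance_additive_along_path(y_network):
    assert hydrologic_distance(y_network, "SA", "SC") + hydrologic_distance(
        y_network, "SC", "SD"
    ) == pytest.approx(hydrologic_distance(y_network, "SA", "SD"))


def test_euclidean_distance(y_network):
    sa, sd = y_network.stations["SA"], y_network.stations["SD"]
    assert euclidean_distance(sa, sd) == pytest.approx(math.hypot(300, 700))


def test_sinuosity_values(y_network):
    assert sinuosity_index(y_network, "SA", "SC") == pytest.approx(1.2)
    assert sinuosity_index(y_network, "SB", "SC") == pytest.approx(1.0)
    assert sinuosity_index(y_network, "SC", "SD") == pytest.approx(4.0 / 3.0)


def test_sinuosity_below_one_raises():
    junctions = [Junction("A", 0, 0), Junction("B", 1000, 0)]
    segments = [Segment("A", "B", 100.0, 1.0)]  # channel shorter than chord
    stations = [StationRecord("S1", "A", 0, 0), StationRecord("S2", "B", 1000, 0)]
    net = RiverNetwork(junctions, segments, stations)
    with pytest.raises(GeometryError):
        sinuosity_index(net, "S1", "S2")


def test_travel_time_values(y_network):
    assert travel_time(y_network, "SA", "SD") == pytest.approx(1700.0)
    assert travel_time(y_network, "SB", "SC") == pytest.approx(500.0)
    assert travel_time(y_network, "SD", "SB") == pytest.approx(
        travel_time(y_network, "SB", "SD")
    )


@pytest.mark.parametrize("seed", range(5))
def test_synth_geometry_invariants(seed):
    net = generate_network(SynthConfig(n_stations=12, seed=seed))
    ids = list(net.stations)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            assert sinuosity_index(net, a, b) >= 1.0
            assert travel_time(net, a, b) > 0


# ---------------------------------------------------------------------- #
# direction relations


def test_direction_relation_y_network(y_network):
    assert direction_relation(y_network, "SA", "SD") == "upstream"
    assert direction_relation(y_network, "SD", "SA") == "downstream"
    assert direction_relation(y_network, "SB", "SD") == "tributary"
    assert direction_relation(y_network, "SD", "SB") == "tributary"
    assert direction_relation(y_network, "SA", "SB") == "different_branch"
    assert direction_relation(y_network, "SA", "SC") == "upstream"


def test_direction_relation_self_raises(y_network):
    with pytest.raises(ValueError):
        direction_relation(y_network, "SA", "SA")


@pytest.mark.parametrize("seed", range(6))
def test_direction_relation_consistency_oracle(seed):
    """upstream <-> downstream mirror; tributary and different_branch are
    symmetric; connectivity class matches a reachability oracle."""
    import networkx as nx

    net = generate_network(SynthConfig(n_stations=12, seed=seed))
    ids = list(net.stations)
    for a in ids:
        for b in ids:
            if a == b:
                continue
            r_ab = direction_relation(net, a, b)
            r_ba = direction_relation(net, b, a)
            if r_ab == "upstream":
                assert r_ba == "downstream"
            elif r_ab == "downstream":
                assert r_ba == "upstream"
            else:
                assert r_ba == r_ab
            ja = net.stations[a].junction_id
            jb = net.stations[b].junction_id
            connected = nx.has_path(net.graph, ja, jb) or nx.has_path(
                net.graph, jb, ja
            )
            if connected:
                assert r_ab in ("upstream", "downstream", "tributary")
            else:
                assert r_ab == "different_branch"


# ---------------------------------------------------------------------- #
# structural validation


def _yj():
    return [Junction("A", 0, 0), Junction("B", 1, 0), Junction("C", 2, 0)]


def test_cycle_rejected():
    segs = [Segment("A", "B", 1.0, 1.0), Segment("B", "C", 1.0, 1.0),
            Segment("C", "A", 1.0, 1.0)]
    with pytest.raises(NetworkStructureError):
        RiverNetwork(_yj(), segs)


def test_out_degree_two_rejected():
    segs = [Segment("A", "B", 1.0, 1.0), Segment("A", "C", 1.0, 1.0)]
    with pytest.raises(NetworkStructureError):
        RiverNetwork(_yj(), segs)


def test_two_outlets_rejected():
    segs = [Segment("A", "B", 1.0, 1.0)]  # C disconnected => second outlet
    with pytest.raises(NetworkStructureError):
        RiverNetwork(_yj(), segs)


def test_unknown_junction_rejected():
    segs = [Segment("A", "Z", 1.0, 1.0)]
    with pytest.raises(NetworkStructureError):
        RiverNetwork(_yj(), segs)


def test_duplicate_station_rejected():
    segs = [Segment("A", "B", 1.0, 1.0), Segment("B", "C", 1.0, 1.0)]
    sts = [StationRecord("S", "A", 0, 0), StationRecord("S", "B", 1, 0)]
    with pytest.raises(NetworkStructureError):
        RiverNetwork(_yj(), segs, sts)


def test_nonpositive_segment_rejected():
    with pytest.raises(ValueError):
        Segment("A", "B", 0.0, 1.0)
    with pytest.raises(ValueError):
        Segment("A", "B", 1.0, -1.0)


def test_negative_bod_rejected():
    with pytest.raises(ValueError):
        StationRecord("S", "A", 0, 0, observations={"BOD5": -1.0})


# ---------------------------------------------------------------------- #
# pairwise features


def test_pairwise_features_hours_scaling(y_network):
    sec = pairwise_features(y_network, time_unit="seconds")
    hrs = pairwise_features(y_network, time_unit="hours")
    assert np.allclose(sec.travel_time, hrs.travel_time * 3600.0)
    assert (np.diag(hrs.relation) == -1).all()
    assert hrs.bod5[hrs.station_ids.index("SA")] == 4.0


def test_pairwise_features_bad_unit(y_network):
    with pytest.raises(ValueError):
        pairwise_features(y_network, time_unit="days")


# ---------------------------------------------------------------------- #
# CSV round-trip


def test_csv_round_trip(tmp_path, y_network):
    write_network_csv(y_network, tmp_path / "e.csv", tmp_path / "j.csv")
    write_stations_csv(y_network.stations.values(), tmp_path / "s.csv")
    junctions, segments = read_network_csv(tmp_path / "e.csv", tmp_path / "j.csv")
    stations = read_stations_csv(tmp_path / "s.csv")
    net2 = RiverNetwork(junctions, segments, stations)
    assert strahler_orders(net2) == strahler_orders(y_network)
    assert net2.stations["SA"].bod5 == 4.0
    f1 = pairwise_features(y_network)
    f2 = pairwise_features(net2, station_ids=f1.station_ids)
    assert np.allclose(f1.travel_time, f2.travel_time)
    assert np.allclose(f1.sinuosity, f2.sinuosity)
    assert (f1.relation == f2.relation).all()
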