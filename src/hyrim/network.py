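"""River-network representation and hydro-geomorphic feature derivation.

A monitoring network is modelled as a dendritic tree: junctions are nodes,
segments are directed edges following flow (upstream -> downstream), every
junction drains through at most one outgoing segment, and the whole network
drains to a single outlet. Monitoring stations are attached to junctions.

From this structure the module derives the four features the interpolation
weight consumes: Strahler stream order, advective travel time along the
channel, the sinuosity index of the connecting path, and the flow-direction
relation between two stations (upstream / downstream / tributary /
different_branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "Segment",
    "StationRecord",
    "RiverNetwork",
    "NetworkStructureError",
    "GeometryError",
    "strahler_orders",
    "path_between",
    "hydrologic_distance",
    "euclidean_distance",
    "sinuosity_index",
    "direction_relation",
    "travel_time",
    "read_network_csv",
    "write_network_csv",
    "read_stations_csv",
    "write_stations_csv",
]

#: Tolerance below which a sinuosity slightly under 1 is attributed to
#: floating-point noise rather than bad geometry.
SI_TOLERANCE = 1e-9

Relation = Literal["upstream", "downstream", "tributary", "different_branch"]

OBSERVATION_COLUMNS = ["BOD5", "T", "DO", "NO3", "Tu", "TS"]


class NetworkStructureError(ValueError):
    """The graph violates the dendritic-tree invariants."""


class GeometryError(ValueError):
    """Station geometry is inconsistent (e.g. channel shorter than chord)."""


@dataclass(frozen=True)
class Junction:
    id: str
    x: float
    y: float


@dataclass(frozen=True)
class Segment:
    """One junction-to-junction reach; direction encodes flow."""

    upstream_junction: str
    downstream_junction: str
    hydrologic_length: float  # meters
    mean_velocity: float  # m/s

    def __post_init__(self) -> None:
        if not self.hydrologic_length > 0:
            raise ValueError(
                f"segment {self.upstream_junction}->{self.downstream_junction}: "
                f"hydrologic_length must be > 0, got {self.hydrologic_length}"
            )
        if not self.mean_velocity > 0:
            raise ValueError(
                f"segment {self.upstream_junction}->{self.downstream_junction}: "
                f"mean_velocity must be > 0, got {self.mean_velocity}"
            )

    @property
    def travel_time(self) -> float:
        """Advective transit time of the reach in seconds."""
        return self.hydrologic_length / self.mean_velocity


@dataclass
class StationRecord:
    """One monitoring site and its observations (BOD5 in mg/L)."""

    id: str
    junction_id: str
    x: float
    y: float
    strahler_order: int | None = None
    zone: str | None = None
    season: str | None = None
    observations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strahler_order is not None and self.strahler_order < 1:
            raise ValueError(f"station {self.id}: strahler_order must be >= 1")
        bod = self.observations.get("BOD5")
        if bod is not None and bod < 0:
            raise ValueError(f"station {self.id}: BOD5 must be >= 0, got {bod}")

    @property
    def bod5(self) -> float | None:
        return self.observations.get("BOD5")


class RiverNetwork:
    """Dendritic river network with attached monitoring stations.

    Parameters
    ----------
    junctions, segments, stations
        Components of the network. Validated on construction: the flow graph
        must be acyclic, every junction must have out-degree <= 1, there must
        be exactly one outlet, and every station's junction must exist.
    """

    def __init__(
        self,
        junctions: Iterable[Junction],
        segments: Iterable[Segment],
        stations: Iterable[StationRecord] = (),
    ) -> None:
        self.junctions: dict[str, Junction] = {}
        for j in junctions:
            if j.id in self.junctions:
                raise NetworkStructureError(f"duplicate junction id {j.id!r}")
            self.junctions[j.id] = j
        self.segments: list[Segment] = list(segments)
        self.stations: dict[str, StationRecord] = {}
        for s in stations:
            if s.id in self.stations:
                raise NetworkStructureError(f"duplicate station id {s.id!r}")
            self.stations[s.id] = s

        g = nx.DiGraph()
        g.add_nodes_from(self.junctions)
        for seg in self.segments:
            for jid in (seg.upstream_junction, seg.downstream_junction):
                if jid not in self.junctions:
                    raise NetworkStructureError(
                        f"segment references unknown junction {jid!r}"
                    )
            if g.has_edge(seg.upstream_junction, seg.downstream_junction):
                raise NetworkStructureError(
                    f"parallel segment {seg.upstream_junction}->"
                    f"{seg.downstream_junction}"
                )
            g.add_edge(seg.upstream_junction, seg.downstream_junction, segment=seg)
        self.graph = g
        self._validate()
        self._undirected = g.to_undirected(as_view=False)
        self._orders: dict[str, int] | None = None
        self._mainstem: dict[str, frozenset[str]] = {}
        self._upstream_length: dict[str, float] | None = None

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        g = self.graph
        for node in g.nodes:
            if g.out_degree(node) > 1:
                raise NetworkStructureError(
                    f"junction {node!r} has out-degree {g.out_degree(node)} > 1; "
                    "a dendritic network drains each junction through one segment"
                )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise NetworkStructureError(f"flow graph contains a cycle at {cycle[0][0]!r}")
        outlets = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(g) and len(outlets) != 1:
            raise NetworkStructureError(
                f"expected a single outlet, found {sorted(outlets)!r}"
            )
        if len(g) > 1 and not nx.is_weakly_connected(g):
            raise NetworkStructureError("network is not connected")
        for s in self.stations.values():
            if s.junction_id not in self.junctions:
                raise NetworkStructureError(
                    f"station {s.id!r} attached to unknown junction {s.junction_id!r}"
                )

    # ------------------------------------------------------------------ #
    # derived quantities

    @property
    def outlet(self) -> str:
        return next(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def junction_orders(self) -> dict[str, int]:
        """Strahler order of every junction (cached)."""
        if self._orders is None:
            orders: dict[str, int] = {}
            for node in nx.topological_sort(self.graph):
                inflow = [orders[p] for p in self.graph.predecessors(node)]
                if not inflow:
                    orders[node] = 1
                else:
                    top = max(inflow)
                    orders[node] = top + 1 if inflow.count(top) >= 2 else top
            self._orders = orders
        return self._orders

    def station_order(self, station_id: str) -> int:
        """Stream order at a station: input value wins, else derived."""
        s = self._station(station_id)
        if s.strahler_order is not None:
            return s.strahler_order
        return self.junction_orders()[s.junction_id]

    def _station(self, station_id: str) -> StationRecord:
        try:
            return self.stations[station_id]
        except KeyError:
            raise KeyError(f"unknown station {station_id!r}") from None

    def _upstream_lengths(self) -> dict[str, float]:
        # total channel length draining to each junction; mainstem tie-break
        if self._upstream_length is None:
            acc: dict[str, float] = {}
            for node in nx.topological_sort(self.graph):
                total = 0.0
                for p in self.graph.predecessors(node):
                    seg: Segment = self.graph.edges[p, node]["segment"]
                    total += acc[p] + seg.hydrologic_length
                acc[node] = total
            self._upstream_length = acc
        return self._upstream_length

    def mainstem_above(self, junction_id: str) -> frozenset[str]:
        """Junctions on the mainstem walk upstream of ``junction_id``.

        At each confluence the walk follows the inflowing branch of highest
        Strahler order; ties go to the branch with the larger upstream
        channel length, then to the lexicographically smaller junction id.
        """
        if junction_id not in self._mainstem:
            orders = self.junction_orders()
            lengths = self._upstream_lengths()
            walk: set[str] = set()
            node = junction_id
            while True:
                preds = list(self.graph.predecessors(node))
                if not preds:
                    break
                node = max(preds, key=lambda p: (orders[p], lengths[p], [-ord(c) for c in p]))
                walk.add(node)
            self._mainstem[junction_id] = frozenset(walk)
        return self._mainstem[junction_id]

    def path_junctions(self, a_junction: str, b_junction: str) -> list[str]:
        """Unique undirected junction path in the tree (inclusive)."""
        try:
            return nx.shortest_path(self._undirected, a_junction, b_junction)
        except nx.NetworkXNoPath:
            raise NetworkStructureError(
                f"junctions {a_junction!r} and {b_junction!r} are disconnected"
            ) from None


# ---------------------------------------------------------------------- #
# operations


def strahler_orders(network: RiverNetwork) -> dict[str, int]:
    """Strahler order of every junction.

    Headwaters get order 1; at a confluence where k is the maximum inflowing
    order, the result is k+1 if at least two inflows attain k, else k.
    """
    return dict(network.junction_orders())


def path_between(network: RiverNetwork, a: str, b: str) -> list[Segment]:
    """Segments on the unique tree path between two stations' junctions.

    Empty when both stations share a junction; segments are returned in
    path order from ``a`` toward ``b``.
    """
    ja = network._station(a).junction_id
    jb = network._station(b).junction_id
    nodes = network.path_junctions(ja, jb)
    segs: list[Segment] = []
    for u, v in zip(nodes, nodes[1:]):
        if network.graph.has_edge(u, v):
            segs.append(network.graph.edges[u, v]["segment"])
        else:
            segs.append(network.graph.edges[v, u]["segment"])
    return segs


def hydrologic_distance(network: RiverNetwork, a: str, b: str) -> float:
    """In-stream (along-channel) distance in meters between two stations."""
    return sum(seg.hydrologic_length for seg in path_between(network, a, b))


def euclidean_distance(a: StationRecord, b: StationRecord) -> float:
    """Straight-line planar distance between two stations in meters."""
    for s in (a, b):
        if s.x is None or s.y is None or math.isnan(s.x) or math.isnan(s.y):
            raise GeometryError(f"station {s.id!r} is missing coordinates")
    return math.hypot(a.x - b.x, a.y - b.y)


def sinuosity_index(network: RiverNetwork, a: str, b: str) -> float:
    """Sinuosity index SI = L_HD / L_E of the path between two stations.

    SI >= 1 for any physically valid channel path. SI < 1 (beyond a 1e-9
    tolerance) signals inconsistent geometry and raises ``GeometryError``
    rather than being clamped.
    """
    sa, sb = network._station(a), network._station(b)
    l_hd = hydrologic_distance(network, a, b)
    l_e = euclidean_distance(sa, sb)
    if l_e == 0.0:
        if l_hd > 0.0:
            raise GeometryError(
                f"stations {a!r}, {b!r}: zero Euclidean distance with "
                f"channel distance {l_hd} m"
            )
        return 1.0
    si = l_hd / l_e
    if si < 1.0 - SI_TOLERANCE:
        raise GeometryError(
            f"stations {a!r}, {b!r}: sinuosity {si:.6g} < 1 "
            "(channel shorter than straight line; check inputs)"
        )
    return max(si, 1.0)


def direction_relation(network: RiverNetwork, neighbor: str, target: str) -> Relation:
    """Flow-direction relation of ``neighbor`` relative to ``target``.

    ``upstream``: the neighbor lies on the target's mainstem and its water
    reaches the target. ``downstream``: the mirror case. ``tributary``: the
    two are flow-connected but joined through a side branch off the mainstem
    (classified symmetrically, so upstream(a,b) holds exactly when
    downstream(b,a) does). ``different_branch``: sub-catchments meet only
    below both stations.
    """
    if neighbor == target:
        raise ValueError("direction relation is undefined for a station and itself")
    jn = network._station(neighbor).junction_id
    jt = network._station(target).junction_id
    if jn == jt:
        raise ValueError(
            f"stations {neighbor!r} and {target!r} share a junction; "
            "relation undefined (co-located)"
        )
    if nx.has_path(network.graph, jn, jt):  # neighbor's water reaches target
        return "upstream" if jn in network.mainstem_above(jt) else "tributary"
    if nx.has_path(network.graph, jt, jn):  # target's water reaches neighbor
        return "downstream" if jt in network.mainstem_above(jn) else "tributary"
    return "different_branch"


def travel_time(network: RiverNetwork, neighbor: str, target: str) -> float:
    """Advective travel time in seconds along the path between two stations."""
    return sum(seg.travel_time for seg in path_between(network, neighbor, target))


# ---------------------------------------------------------------------- #
# pairwise feature tables (consumed by the interpolation model)

RELATION_CODES: Mapping[Relation, int] = {
    "upstream": 0,
    "downstream": 1,
    "tributary": 2,
    "different_branch": 3,
}


@dataclass
class PairwiseFeatures:
    """Dense station-pair feature tables for vectorized prediction.

    ``travel_time`` is in the unit given by ``time_unit``; entries on the
    diagonal are zero and must never be consumed as weights.
    """

    station_ids: list[str]
    order: np.ndarray  # (n,) neighbor stream order
    travel_time: np.ndarray  # (n, n) [i, j] = time from j to i
    sinuosity: np.ndarray  # (n, n)
    relation: np.ndarray  # (n, n) int codes, RELATION_CODES; -1 on diagonal
    bod5: np.ndarray  # (n,) observed BOD5, NaN if absent
    time_unit: str = "hours"


def pairwise_features(
    network: RiverNetwork,
    station_ids: list[str] | None = None,
    time_unit: str = "hours",
) -> PairwiseFeatures:
    """Precompute all station-pair features needed by the weight function."""
    if time_unit not in ("seconds", "hours"):
        raise ValueError(f"time_unit must be 'seconds' or 'hours', got {time_unit!r}")
    ids = list(station_ids) if station_ids is not None else list(network.stations)
    n = len(ids)
    scale = 1.0 if time_unit == "seconds" else 1.0 / 3600.0
    order = np.array([network.station_order(s) for s in ids], dtype=float)
    tt = np.zeros((n, n))
    si = np.ones((n, n))
    rel = np.full((n, n), -1, dtype=int)
    bod = np.array(
        [network._station(s).bod5 if network._station(s).bod5 is not None else np.nan
         for s in ids]
    )
    for i, target in enumerate(ids):
        for j, neigh in enumerate(ids):
            if i == j:
                continue
            tt[i, j] = travel_time(network, neigh, target) * scale
            si[i, j] = sinuosity_index(network, neigh, target)
            jn = network._station(neigh).junction_id
            jt = network._station(target).junction_id
            if jn == jt:
                rel[i, j] = RELATION_CODES["upstream"]  # co-located; weight unused
            else:
                rel[i, j] = RELATION_CODES[direction_relation(network, neigh, target)]
    return PairwiseFeatures(ids, order, tt, si, rel, bod, time_unit)


# ---------------------------------------------------------------------- #
# CSV interfaces

STATION_COLUMNS = [
    "station_id", "junction_id", "x", "y", "strahler_order", "zone", "season",
] + OBSERVATION_COLUMNS


def read_network_csv(edges_path, junctions_path) -> tuple[list[Junction], list[Segment]]:
    """Read the edge list and junction coordinate tables.

    Edge CSV columns: ``upstream_junction,downstream_junction,length_m,velocity_mps``.
    Junction CSV columns: ``junction_id,x,y``.
    """
    jdf = pd.read_csv(junctions_path, dtype={"junction_id": str})
    junctions = [
        Junction(r.junction_id, float(r.x), float(r.y)) for r in jdf.itertuples()
    ]
    edf = pd.read_csv(
        edges_path, dtype={"upstream_junction": str, "downstream_junction": str}
    )
    segments = [
        Segment(r.upstream_junction, r.downstream_junction,
                float(r.length_m), float(r.velocity_mps))
        for r in edf.itertuples()
    ]
    return junctions, segments


def write_network_csv(network: RiverNetwork, edges_path, junctions_path) -> None:
    pd.DataFrame(
        [
            {
                "upstream_junction": s.upstream_junction,
                "downstream_junction": s.downstream_junction,
                "length_m": s.hydrologic_length,
                "velocity_mps": s.mean_velocity,
            }
            for s in network.segments
        ]
    ).to_csv(edges_path, index=False)
    pd.DataFrame(
        [{"junction_id": j.id, "x": j.x, "y": j.y} for j in network.junctions.values()]
    ).to_csv(junctions_path, index=False)


def read_stations_csv(path) -> list[StationRecord]:
    """Read the station table (header required; missing values empty)."""
    df = pd.read_csv(path, dtype={"station_id": str, "junction_id": str})
    missing = {"station_id", "junction_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"stations CSV missing required columns: {sorted(missing)}")
    stations = []
    for r in df.itertuples():
        obs = {}
        for col in OBSERVATION_COLUMNS:
            if col in df.columns:
                v = getattr(r, col)
                if pd.notna(v):
                    obs[col] = float(v)
        so = getattr(r, "strahler_order", None)
        zone = getattr(r, "zone", None)
        season = getattr(r, "season", None)
        stations.append(
            StationRecord(
                id=r.station_id,
                junction_id=r.junction_id,
                x=float(r.x),
                y=float(r.y),
                strahler_order=int(so) if pd.notna(so) else None,
                zone=str(zone) if pd.notna(zone) else None,
                season=str(season) if pd.notna(season) else None,
                observations=obs,
            )
        )
    return stations


def write_stations_csv(stations: Iterable[StationRecord], path) -> None:
    rows = []
    for s in stations:
        row = {
            "station_id": s.id,
            "junction_id": s.junction_id,
            "x": s.x,
            "y": s.y,
            "strahler_order": s.strahler_order,
            "zone": s.zone,
            "season": s.season,
        }
        for col in OBSERVATION_COLUMNS:
            row[col] = s.observations.get(col)
        rows.append(row)
    pd.DataFrame(rows, columns=STATION_COLUMNS).to_csv(path, index=False)
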