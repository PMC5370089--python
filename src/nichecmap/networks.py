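"""Shortest-path subnetwork extraction over a typed interaction graph.

Target genes of a screened drug act as seeds on a directed, typed
gene/protein graph. All shortest paths between seed pairs are enumerated with
Dijkstra's algorithm (all tied predecessors retained) and added to the
subnetwork in ascending path-length strata until the next stratum would push
the node count past the cap (70-80 nodes by default). Whole strata are added
or skipped — never truncated — so the extract is independent of enumeration
order, and the node set at a smaller cap is always a subset of the node set
at a larger one.

An optional signaling-to-transcription filter keeps only seed pairs whose
source role is ligand/receptor/kinase and whose target role is
transcription-factor/target-gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

SIGNALING_ROLES = frozenset({"ligand", "receptor", "kinase"})
TRANSCRIPTION_ROLES = frozenset({"transcription-factor", "target-gene"})


class NetworkError(ValueError):
    pass


@dataclass
class Subnetwork:
    nodes: set[str]
    edges: set[tuple[str, str]]
    paths: dict[tuple[str, str], list[list[str]]]
    seeds_in_graph: list[str]
    seeds_missing: list[str] = field(default_factory=list)
    disconnected_pairs: list[tuple[str, str]] = field(default_factory=list)
    below_cap_min: bool = False

    def to_graph(self, graph: nx.DiGraph) -> nx.DiGraph:
        sub = graph.subgraph(self.nodes).copy()
        return sub.edge_subgraph(self.edges).copy() if self.edges else sub


def shortest_paths(graph: nx.DiGraph, source: str):
    """Single-source Dijkstra distances plus all shortest predecessors.

    Unreachable nodes simply do not appear in the distance map (an infinite
    distance sentinel). Edges default to weight 1; any negative weight is
    rejected because Dijkstra's invariants require non-negative weights.
    """
    for u, v, d in graph.edges(data=True):
        if d.get("weight", 1) < 0:
            raise NetworkError(f"negative edge weight on ({u!r}, {v!r})")
    if source not in graph:
        raise NetworkError(f"source {source!r} not in graph")
    pred, dist = nx.dijkstra_predecessor_and_distance(graph, source,
                                                      weight="weight")
    return dist, pred


def _paths_from_predecessors(pred: dict, source: str, target: str) -> list[list[str]]:
    """Enumerate every shortest path source->target from the predecessor DAG."""
    if target == source:
        return [[source]]
    if target not in pred or not pred[target]:
        return []
    out = []
    for p in pred[target]:
        for head in _paths_from_predecessors(pred, source, p):
            out.append(head + [target])
    return out


def extract_subnetwork(graph: nx.DiGraph, seeds: Iterable[str],
                       cap_min: int = 70, cap_max: int = 80,
                       signaling_to_tf: bool = False) -> Subnetwork:
    """Node-capped union of all shortest paths between seed pairs.

    Ordered seed pairs (s, t), s != t, are connected by every tied shortest
    directed path. Paths group into strata by exact path length (total edge
    weight); strata join the subnetwork in ascending order while the node
    union stays within ``cap_max``. If even the full union falls short of
    ``cap_min`` it is returned as-is, flagged. Disconnected seed pairs are
    reported, not dropped silently.
    """
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in graph]
    missing = [s for s in seeds if s not in graph]
    if len(present) < 2:
        raise NetworkError(
            f"need at least 2 seeds in the graph, found {len(present)}")
    if cap_max < len(present):
        raise NetworkError("cap below seed count")
    if cap_min > cap_max:
        raise NetworkError("cap_min exceeds cap_max")

    roles = nx.get_node_attributes(graph, "role")

    def pair_allowed(s: str, t: str) -> bool:
        if not signaling_to_tf:
            return True
        return (roles.get(s) in SIGNALING_ROLES
                and roles.get(t) in TRANSCRIPTION_ROLES)

    # all tied shortest paths per ordered pair, grouped by exact length
    strata: dict[float, list[tuple[tuple[str, str], list[str]]]] = {}
    disconnected: list[tuple[str, str]] = []
    for s in present:
        dist, pred = shortest_paths(graph, s)
        for t in present:
            if t == s or not pair_allowed(s, t):
                continue
            if t not in dist:
                disconnected.append((s, t))
                continue
            for path in _paths_from_predecessors(pred, s, t):
                strata.setdefault(dist[t], []).append(((s, t), path))

    nodes: set[str] = set(present)
    edges: set[tuple[str, str]] = set()
    paths: dict[tuple[str, str], list[list[str]]] = {}
    for length in sorted(strata):
        stratum = strata[length]
        tentative = nodes | {n for _, path in stratum for n in path}
        if len(tentative) > cap_max:
            break
        nodes = tentative
        for pair, path in stratum:
            paths.setdefault(pair, []).append(path)
            edges.update(zip(path[:-1], path[1:]))

    return Subnetwork(nodes=nodes, edges=edges, paths=paths,
                      seeds_in_graph=present, seeds_missing=missing,
                      disconnected_pairs=sorted(disconnected),
                      below_cap_min=len(nodes) < cap_min)
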