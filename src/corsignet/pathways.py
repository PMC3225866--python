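"""Receptor-to-transcription-factor pathway extraction.

A pathway is the single minimum-distance path between one receptor and one
transcription factor in the correlation-weighted network (Dijkstra on the
``distance`` edge attribute).  Ties among equal-distance optima are broken
deterministically: fewer hops first, then the lexicographically smallest
node sequence.  The signaling network is the sub-network of links used by
at least one pathway, restricted to its largest connected component; link
and node frequencies (a receptor/TF-restricted betweenness) are counted on
that component only, and pathways that lost links to the restriction are
dropped.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import networkx as nx

from .io import GeneSet, normalize_link

logger = logging.getLogger(__name__)

_DIST_TOL = 1e-9


@dataclass(frozen=True)
class Pathway:
    """One shortest receptor-to-TF path."""

    receptor: str
    tf: str
    nodes: tuple[str, ...]
    total_distance: float

    def __post_init__(self) -> None:
        if self.nodes[0] != self.receptor or self.nodes[-1] != self.tf:
            raise ValueError("pathway node sequence must run receptor -> tf")
        if len(self.nodes) < 2:
            raise ValueError("pathway needs at least one hop")

    @property
    def hops(self) -> int:
        return len(self.nodes) - 1

    @property
    def links(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            normalize_link(a, b) for a, b in zip(self.nodes, self.nodes[1:])
        )


@dataclass(frozen=True)
class PathwaySet:
    """At most one pathway per (receptor, tf) pair."""

    pathways: dict[tuple[str, str], Pathway]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, key: tuple[str, str]) -> Pathway:
        return self.pathways[key]


@dataclass(frozen=True)
class SignalingNetwork:
    """Pathway-pruned largest connected component with usage counts."""

    graph: nx.Graph
    pathways: PathwaySet
    link_freq: dict[tuple[str, str], int]
    node_freq: dict[str, int]
    fraction_links_used: float
    fraction_nodes_used: float

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _single_source_best(net: nx.Graph, source: str) -> dict[str, tuple]:
    """Dijkstra keyed by (distance, hops, node sequence).

    The composite key makes the selected optimum unique and deterministic:
    the heap pops the lexicographically smallest (d, hops, path) tuple, and
    every prefix of an optimal key is itself optimal, so first-pop wins.
    """
    best: dict[str, tuple] = {}
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    while heap:
        d, h, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (d, h, path)
        for nbr, attrs in net[node].items():
            if nbr not in best:
                heapq.heappush(heap, (d + attrs["distance"], h + 1, path + (nbr,)))
    return best


def dijkstra_shortest_path(net: nx.Graph, source: str, target: str) -> Pathway | None:
    """Minimum-distance path from ``source`` to ``target``, or None.

    Among equal-distance optima the deterministic tie rule applies (fewer
    hops, then lexicographically smallest node sequence).
    """
    if source == target:
        raise ValueError("source and target coincide")
    for node in (source, target):
        if node not in net:
            raise KeyError(f"node {node!r} not in network")
    best = _single_source_best(net, source)
    if target not in best:
        return None
    d, _h, path = best[target]
    return Pathway(receptor=source, tf=target, nodes=path, total_distance=d)


def extract_pathways(net: nx.Graph, receptors: GeneSet, tfs: GeneSet) -> PathwaySet:
    """One pathway per reachable (receptor, TF) pair.

    Role genes absent from the network and pairs where the same gene holds
    both roles are skipped; unreachable pairs are simply absent.
    """
    if not receptors.symbols or not tfs.symbols:
        raise ValueError("receptor and TF sets must be non-empty")
    rs = sorted(s for s in receptors.symbols if s in net)
    ts = sorted(s for s in tfs.symbols if s in net)
    found: dict[tuple[str, str], Pathway] = {}
    for r in rs:
        best = _single_source_best(net, r)
        for t in ts:
            if t == r or t not in best:
                continue
            d, _h, path = best[t]
            found[(r, t)] = Pathway(receptor=r, tf=t, nodes=path, total_distance=d)
    if not found:
        raise ValueError("no receptor-TF pair is connected in the network")
    return PathwaySet(found)


def build_signaling_network(net: nx.Graph, paths: PathwaySet) -> SignalingNetwork:
    """Prune to pathway-used links, keep the largest connected component.

    Frequencies count, for every surviving link and node, the number of
    retained pathways it lies on (endpoints included).  Component-size ties
    break toward the component containing the smallest node label.
    """
    if len(paths) == 0:
        raise ValueError("empty pathway set")
    used_links = set()
    for p in paths:
        used_links |= p.links
    pruned = nx.Graph()
    for a, b in used_links:
        pruned.add_edge(a, b, **net.edges[a, b])
    components = sorted(nx.connected_components(pruned), key=lambda c: (-len(c), min(c)))
    lcc = components[0]
    if len(components) > 1:
        logger.info(
            "pruned network has %d components; keeping largest (%d nodes)",
            len(components), len(lcc),
        )
    graph = pruned.subgraph(lcc).copy()

    kept: dict[tuple[str, str], Pathway] = {}
    link_freq: dict[tuple[str, str], int] = {}
    node_freq: dict[str, int] = {}
    for key, p in paths.pathways.items():
        if not all(n in lcc for n in p.nodes):
            continue
        kept[key] = p
        for link in p.links:
            link_freq[link] = link_freq.get(link, 0) + 1
        for n in p.nodes:
            node_freq[n] = node_freq.get(n, 0) + 1
    if not kept:
        raise ValueError("no pathway survived the largest-component restriction")

    # links inside the LCC but used only by dropped pathways would have
    # frequency 0; prune them too so every link has frequency >= 1
    zero = [e for e in graph.edges if normalize_link(*e) not in link_freq]
    if zero:
        graph.remove_edges_from(zero)
        graph.remove_nodes_from(list(nx.isolates(graph)))

    return SignalingNetwork(
        graph=graph,
        pathways=PathwaySet(kept),
        link_freq=link_freq,
        node_freq=node_freq,
        fraction_links_used=graph.number_of_edges() / net.number_of_edges(),
        fraction_nodes_used=graph.number_of_nodes() / net.number_of_nodes(),
    )
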