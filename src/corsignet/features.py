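"""Per-cohort topology and regulation features of a signaling network.

The feature panel mirrors what is compared between tumor and normal
cohorts: network size, pathway-usage frequencies, mean pathway hop length,
Shannon entropy of link traffic, clustering coefficients, the power-law
exponent of the link-frequency distribution, the mean-shortest-path
"diameter" and its increase after removing the top hubs, and the mean link
distance.

Conventions (the underlying study leaves these open; they are fixed here
and documented in the methods note):

* pathway length is the hop count of the distance-optimal path;
* the diameter is the mean hop distance over reachable node pairs,
  unreachable pairs excluded;
* clustering uses C = 2L / (k(k-1)), 0 when k < 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pathways import PathwaySet, SignalingNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTable:
    """Link/node pathway-usage counts (a receptor/TF-restricted betweenness)."""

    link_freq: dict[tuple[str, str], int]
    node_freq: dict[str, int]
    pathway_count: int

    @property
    def avg_link_freq(self) -> float:
        return sum(self.link_freq.values()) / len(self.link_freq)

    @property
    def avg_node_freq(self) -> float:
        return sum(self.node_freq.values()) / len(self.node_freq)


@dataclass(frozen=True)
class FeatureVector:
    """One cohort's feature panel."""

    n_links: int
    n_nodes: int
    avg_link_freq: float
    avg_node_freq: float
    avg_path_length: float
    entropy_bits: float
    avg_clustering: float
    n_nodes_clustering_positive: int
    alpha: float
    diameter: float
    diameter_ratio_after_hub_removal: float
    avg_link_distance: float
    pct_used_nodes: float
    pct_used_links: float


def link_node_frequencies(paths: PathwaySet) -> FrequencyTable:
    """Count, per link and node, the pathways it lies on (endpoints included)."""
    if len(paths) == 0:
        raise ValueError("empty pathway set")
    link_freq: dict[tuple[str, str], int] = {}
    node_freq: dict[str, int] = {}
    for p in paths:
        for link in p.links:
            link_freq[link] = link_freq.get(link, 0) + 1
        for n in p.nodes:
            node_freq[n] = node_freq.get(n, 0) + 1
    return FrequencyTable(link_freq=link_freq, node_freq=node_freq, pathway_count=len(paths))


def average_path_length(paths: PathwaySet) -> float:
    """Arithmetic mean of pathway hop counts."""
    if len(paths) == 0:
        raise ValueError("empty pathway set")
    return sum(p.hops for p in paths) / len(paths)


def shannon_entropy(link_freq: dict | FrequencyTable) -> float:
    """Shannon entropy (bits) of pathway traffic over links.

    A signal is assumed to traverse link i with probability proportional to
    the number of pathways using it: p_i = f_i / sum(f), and
    I = -sum_i p_i log2 p_i, bounded by log2(n_links).
    """
    if isinstance(link_freq, FrequencyTable):
        counts = np.array(list(link_freq.link_freq.values()), dtype=float)
    else:
        counts = np.array(list(link_freq.values()), dtype=float)
    if counts.size == 0:
        raise ValueError("no links")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def clustering_coefficient(net: nx.Graph, node: str) -> float:
    """C = 2L / (k(k-1)) over the node's neighborhood; 0 when k < 2."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(net, node))


def count_clustering_positive(net: nx.Graph) -> int:
    """Number of nodes with clustering coefficient > 0."""
    return sum(1 for c in nx.clustering(net).values() if c > 0)


def estimate_powerlaw_exponent(
    freqs, fmin: float | None = None, discrete: bool = False
) -> float:
    """Power-law exponent of a frequency distribution P(f) ~ f^-alpha.

    Continuous maximum-likelihood estimator (equivalently, the exponent of
    the cumulative distribution): alpha = 1 + n / sum(ln(f_i / fmin)) with
    fmin the smallest observed frequency unless given.  ``discrete=True``
    applies the half-step offset fmin - 0.5 recommended for integer data.
    """
    f = np.asarray(list(freqs), dtype=float)
    if f.size < 10:
        raise ValueError(f"need >= 10 frequencies, got {f.size}")
    if (f <= 0).any():
        raise ValueError("frequencies must be positive")
    if fmin is None:
        fmin = float(f.min())
    f = f[f >= fmin]
    denom = fmin - 0.5 if discrete else fmin
    s = float(np.log(f / denom).sum())
    if s == 0.0:
        raise ValueError("all frequencies equal fmin; exponent undefined")
    return 1.0 + f.size / s


def powerlaw_loglog_fit(freqs) -> tuple[float, float]:
    """Least-squares (slope, intercept) of the log-log frequency histogram.

    Visualization companion only — the exponent itself comes from
    :func:`estimate_powerlaw_exponent`.
    """
    f = np.asarray(list(freqs), dtype=float)
    vals, counts = np.unique(f, return_counts=True)
    x = np.log10(vals)
    y = np.log10(counts / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def network_diameter(net: nx.Graph) -> float:
    """Mean hop distance over all reachable unordered node pairs."""
    if net.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    total = 0
    n_pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            if target > source:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no reachable node pair")
    return total / n_pairs


def hub_removal_robustness(
    net: nx.Graph, node_freq: dict[str, int], fraction: float = 0.10
) -> float:
    """Diameter ratio after removing the top-frequency hubs.

    Removes max(1, floor(fraction * n_nodes)) nodes of highest node
    frequency (ties by frequency then lexicographic), recomputes the mean
    shortest-path diameter on the remaining largest component, and returns
    diameter_after / diameter_before.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    before = network_diameter(net)
    n_remove = max(1, math.floor(fraction * net.number_of_nodes()))
    ranked = sorted(net.nodes, key=lambda n: (-node_freq.get(n, 0), n))
    survivor = net.copy()
    survivor.remove_nodes_from(ranked[:n_remove])
    if survivor.number_of_nodes() < 2:
        raise ValueError("hub removal emptied the network")
    components = sorted(
        nx.connected_components(survivor), key=lambda c: (-len(c), min(c))
    )
    lcc = survivor.subgraph(components[0])
    if lcc.number_of_nodes() < 2:
        raise ValueError("largest surviving component has < 2 nodes")
    return network_diameter(lcc) / before


def signaling_features(
    signet: SignalingNetwork,
    full_net: nx.Graph,
    hub_removal_fraction: float = 0.10,
) -> FeatureVector:
    """Assemble the full per-cohort feature panel."""
    freq = FrequencyTable(
        link_freq=signet.link_freq,
        node_freq=signet.node_freq,
        pathway_count=len(signet.pathways),
    )
    try:
        alpha = estimate_powerlaw_exponent(freq.link_freq.values())
    except ValueError as exc:
        logger.warning("power-law exponent undefined: %s", exc)
        alpha = math.nan
    # mean link distance is reported on the full weighted network: it
    # characterizes the cohort's co-regulation before pathway pruning
    distances = [d for _, _, d in full_net.edges(data="distance")]
    return FeatureVector(
        n_links=signet.n_links,
        n_nodes=signet.n_nodes,
        avg_link_freq=freq.avg_link_freq,
        avg_node_freq=freq.avg_node_freq,
        avg_path_length=average_path_length(signet.pathways),
        entropy_bits=shannon_entropy(freq),
        avg_clustering=float(np.mean(list(nx.clustering(signet.graph).values()))),
        n_nodes_clustering_positive=count_clustering_positive(signet.graph),
        alpha=alpha,
        diameter=network_diameter(signet.graph),
        diameter_ratio_after_hub_removal=hub_removal_robustness(
            signet.graph, signet.node_freq, hub_removal_fraction
        ),
        avg_link_distance=float(np.mean(distances)),
        pct_used_nodes=100.0 * signet.fraction_nodes_used,
        pct_used_links=100.0 * signet.fraction_links_used,
    )
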