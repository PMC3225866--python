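"""Synthetic paired cohorts over a scale-free interaction network.

The generator provides everything the analysis consumes without external
downloads: a preferential-attachment interaction network, disjoint
receptor/TF role assignments, and two expression cohorts whose edge-wise
absolute correlations follow a configurable law.  The "tumor" cohort is
obtained by multiplying every edge's target correlation by an attenuation
factor ``lam`` in [0, 1], emulating the weaker tumor co-regulation (higher
link distances) seen in real cohort pairs.

Correlations are imposed on a breadth-first spanning tree by Gaussian
propagation (child = rho * parent + sqrt(1 - rho^2) * noise), because an
arbitrary edge-wise correlation assignment on a cyclic graph need not be
positive definite.  Non-tree edges acquire emergent correlations that are
measured by the analysis, not asserted by the generator.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, InteractionSet, normalize_link

RhoLaw = Callable[[np.random.Generator, int], np.ndarray]


def uniform_rho_law(low: float = 0.35, high: float = 0.95) -> RhoLaw:
    """Uniform law over target |rho|; the default spans realistic normal-tissue
    co-regulation (mean 0.65, i.e. mean link distance 0.35)."""
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError("need 0 <= low <= high <= 1")
    return lambda rng, size: rng.uniform(low, high, size)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort pair."""

    n_nodes: int = 300
    attachment_links: int = 2
    n_receptors: int = 20
    n_tfs: int = 15
    n_samples: int = 200
    attenuation: float = 0.3
    edge_rho_law: RhoLaw = field(default_factory=uniform_rho_law)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.attachment_links < self.n_nodes:
            raise ValueError("need 1 <= attachment_links < n_nodes")
        if self.n_receptors + self.n_tfs > self.n_nodes:
            raise ValueError("more roles than nodes")
        if self.n_samples < 3:
            raise ValueError("need >= 3 samples per cohort")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_scale_free_network(n: int, m: int, seed: int) -> InteractionSet:
    """Connected preferential-attachment (Barabasi-Albert) network."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    links = frozenset(
        normalize_link(_gene_name(a), _gene_name(b)) for a, b in g.edges
    )
    return InteractionSet(links)


def assign_roles(
    net: InteractionSet, n_receptors: int, n_tfs: int, seed: int
) -> tuple[GeneSet, GeneSet]:
    """Uniformly sampled disjoint receptor and TF sets."""
    nodes = sorted(net.nodes)
    if n_receptors + n_tfs > len(nodes):
        raise ValueError("more roles than network nodes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(nodes), size=n_receptors + n_tfs, replace=False)
    receptors = frozenset(nodes[i] for i in chosen[:n_receptors])
    tfs = frozenset(nodes[i] for i in chosen[n_receptors:])
    return (
        GeneSet(role="receptor", symbols=receptors),
        GeneSet(role="transcription_factor", symbols=tfs),
    )


def _bfs_tree_order(net: InteractionSet) -> tuple[str, list[tuple[str, str]]]:
    """Deterministic BFS spanning tree (root = smallest node label).

    Returns (root, [(parent, child), ...]) in visit order; assumes the
    network is connected (true for preferential attachment).
    """
    adj: dict[str, list[str]] = {}
    for a, b in net.links:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    root = min(adj)
    seen = {root}
    order: list[tuple[str, str]] = []
    queue = deque([root])
    while queue:
        node = queue.popleft()
        for nbr in sorted(adj[node]):
            if nbr not in seen:
                seen.add(nbr)
                order.append((node, nbr))
                queue.append(nbr)
    if len(seen) < len(adj):
        raise ValueError("interaction network is not connected")
    return root, order


def simulate_cohort(
    net: InteractionSet,
    edge_rho_targets: dict[tuple[str, str], float],
    n_samples: int,
    seed: int,
) -> ExpressionMatrix:
    """One cohort by Gaussian propagation along a BFS spanning tree.

    The root gene is standard normal per sample; each child equals
    rho * parent + sqrt(1 - rho^2) * fresh noise, so the population
    correlation on every tree edge equals its target.  Targets must cover
    at least the spanning tree; non-tree edges are emergent.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    for link, rho in edge_rho_targets.items():
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"target |rho| {rho} for link {link} outside [0, 1]")
    root, order = _bfs_tree_order(net)
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {root: rng.standard_normal(n_samples)}
    for parent, child in order:
        link = normalize_link(parent, child)
        if link not in edge_rho_targets:
            raise ValueError(f"no correlation target for spanning-tree edge {link}")
        rho = edge_rho_targets[link]
        if rho == 1.0:
            values[child] = values[parent].copy()
        else:
            noise = rng.standard_normal(n_samples)
            values[child] = rho * values[parent] + np.sqrt(1.0 - rho**2) * noise
    genes = sorted(values)
    data = pd.DataFrame(
        np.vstack([values[g] for g in genes]),
        index=genes,
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(data)


def generate_paired_cohorts(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, InteractionSet, tuple[GeneSet, GeneSet]]:
    """Normal and tumor cohorts over one network with attenuated tumor targets.

    The normal cohort draws edge targets from ``spec.edge_rho_law``; the
    tumor cohort multiplies every target by ``spec.attenuation``.  All
    randomness derives from ``spec.seed`` (network, roles, targets, and
    independent sampling noise per cohort); attenuation 1 yields two
    identically distributed, independently sampled cohorts.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(5) % (2**31)
    net = generate_scale_free_network(
        spec.n_nodes, spec.attachment_links, seed=int(seeds[0])
    )
    roles = assign_roles(net, spec.n_receptors, spec.n_tfs, seed=int(seeds[1]))
    rng = np.random.default_rng(int(seeds[2]))
    links = sorted(net.links)
    targets = dict(zip(links, spec.edge_rho_law(rng, len(links))))
    tumor_targets = {l: r * spec.attenuation for l, r in targets.items()}
    normal = simulate_cohort(net, targets, spec.n_samples, seed=int(seeds[3]))
    tumor = simulate_cohort(net, tumor_targets, spec.n_samples, seed=int(seeds[4]))
    return normal, tumor, net, roles
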