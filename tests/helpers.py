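"""Independent oracles used by unit and acceptance tests.

Everything here deliberately avoids the library's own code paths:
shortest paths by exhaustive simple-path enumeration, signed-rank tails by
enumerating all 2^n sign assignments, motif counts by raw triple/pair
loops, Fisher p by the hypergeometric survival function.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats as sps


def random_weighted_graph(
    rng: np.random.Generator, n_max: int = 10, p_edge: float = 0.4,
    grid_weights: bool = False,
) -> nx.Graph:
    """Random undirected graph with ``distance`` edge weights in (0, 1].

    ``grid_weights`` draws weights on a 1/64 grid so that path sums are
    exact in binary floating point.
    """
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                if grid_weights:
                    w = float(rng.integers(1, 65)) / 64.0
                else:
                    w = float(rng.uniform(0.01, 1.0))
                g.add_edge(f"N{i}", f"N{j}", distance=w, rho=1.0 - w)
    return g


def brute_force_shortest(g: nx.Graph, source: str, target: str):
    """Minimum (distance, hops, node sequence) over all simple paths.

    Partial sums accumulate left-to-right, matching the addition order of
    a Dijkstra relaxation, so float comparisons are reproducible.
    """
    best = None
    for path in nx.all_simple_paths(g, source, target):
        d = 0.0
        for a, b in zip(path, path[1:]):
            d = d + g.edges[a, b]["distance"]
        key = (d, len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    return best


def enum_signed_rank_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d), method="ordinal").astype(int)
    w_obs = int(ranks[d > 0].sum())
    ws = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=len(ranks))
    ]
    ws = np.asarray(ws)
    lower = float((ws <= w_obs).mean())
    upper = float((ws >= w_obs).mean())
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_triangles(gn: nx.Graph, gt: nx.Graph, hubs) -> list[tuple]:
    """All (hub, n1, n2) with all three links present in both graphs."""
    out = []
    nodes = sorted(set(gn) & set(gt))
    for hub in sorted(hubs):
        if hub not in nodes:
            continue
        for n1, n2 in itertools.combinations([n for n in nodes if n != hub], 2):
            if all(
                g.has_edge(a, b)
                for g in (gn, gt)
                for a, b in ((hub, n1), (hub, n2), (n1, n2))
            ):
                out.append((hub, n1, n2))
    return out


def brute_force_comparative(paths_n, paths_t) -> tuple[int, int]:
    """Comparative motif counts by scanning every (tf, receptor pair)."""
    def links_of(p):
        return {tuple(sorted(e)) for e in zip(p.nodes, p.nodes[1:])}

    keys_n = set(paths_n.pathways)
    keys_t = set(paths_t.pathways)
    tfs = {t for _, t in keys_n} | {t for _, t in keys_t}
    recs = {r for r, _ in keys_n} | {r for r, _ in keys_t}
    normal = tumor = 0
    for tf in sorted(tfs):
        for r1, r2 in itertools.combinations(sorted(recs), 2):
            keys = [(r1, tf), (r2, tf)]
            if not all(k in keys_n and k in keys_t for k in keys):
                continue
            sn = bool(links_of(paths_n[keys[0]]) & links_of(paths_n[keys[1]]))
            st = bool(links_of(paths_t[keys[0]]) & links_of(paths_t[keys[1]]))
            if sn and not st:
                normal += 1
            elif st and not sn:
                tumor += 1
    return normal, tumor


def hypergeom_tail_p(n_universe: int, n_query: int, n_reference: int, overlap: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(universe, reference, query draws)."""
    return float(sps.hypergeom.sf(overlap - 1, n_universe, n_reference, n_query))
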