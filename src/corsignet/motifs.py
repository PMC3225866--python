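"""Hub-centred triangle motifs and the comparative pathway motif.

Three bespoke counters contrast how signaling regulation is organized in
two cohorts (canonically normal vs tumor):

* **integration motif** — a triangle around a cancer-mutated hub whose
  three links are all highly correlated in a cohort: the hub is
  regulatorily integrated with its neighborhood.
* **maintenance motif** — a triangle whose two hub links are highly
  correlated in one cohort and uncorrelated in the other while the
  neighbor-neighbor link keeps its category: the hub is detached but its
  vicinity keeps regulating.  The count is attributed to the cohort in
  which the hub is DE-correlated (so tumors with detached hubs raise the
  tumor column).
* **comparative motif** — two receptors converging on the same TF whose
  two pathways share at least one link in one cohort and none in the
  other.  Sharing a node without a common link does not count.

Triangles are only counted when all three links exist in both cohorts'
signaling networks, keeping the two columns comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .correlation import Category, correlation_category
from .features import FrequencyTable
from .io import GeneSet, normalize_link
from .pathways import PathwaySet, SignalingNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TriangleRecord:
    """A hub-anchored triangle present in both cohort networks.

    ``rho_normal`` / ``rho_tumor`` map each of the three links (sorted node
    pairs) to its signed correlation in the respective cohort.
    """

    hub: str
    n1: str
    n2: str
    rho_normal: dict[tuple[str, str], float]
    rho_tumor: dict[tuple[str, str], float]

    @property
    def hub_links(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return normalize_link(self.hub, self.n1), normalize_link(self.hub, self.n2)

    @property
    def neighbor_link(self) -> tuple[str, str]:
        return normalize_link(self.n1, self.n2)

    def categories(
        self, cohort: str, bounds: tuple[float, float] = (0.3, 0.5)
    ) -> dict[tuple[str, str], Category]:
        rho = self.rho_normal if cohort == "normal" else self.rho_tumor
        return {link: correlation_category(r, bounds) for link, r in rho.items()}


@dataclass(frozen=True)
class MotifCounts:
    integration: tuple[int, int]  # (normal, tumor)
    maintenance: tuple[int, int]
    comparative: tuple[int, int]


def select_cancer_hubs(
    freq_normal: FrequencyTable,
    freq_tumor: FrequencyTable,
    cancer_genes: GeneSet | None,
    k: int = 50,
) -> frozenset[str]:
    """Top-k most pathway-involved cancer-mutated nodes, per cohort, united.

    Candidates are the cancer-mutated genes present in both cohorts'
    frequency tables (``cancer_genes=None`` disables the mutation filter).
    Each cohort contributes its top-k candidates by node frequency (ties
    broken lexicographically); a node selected in both cohorts counts once.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shared = set(freq_normal.node_freq) & set(freq_tumor.node_freq)
    if cancer_genes is not None:
        shared &= cancer_genes.symbols
    if not shared:
        logger.warning("no cancer-mutated gene occurs in both cohort networks")
        return frozenset()
    top_n = sorted(shared, key=lambda g: (-freq_normal.node_freq[g], g))[:k]
    top_t = sorted(shared, key=lambda g: (-freq_tumor.node_freq[g], g))[:k]
    return frozenset(top_n) | frozenset(top_t)


def enumerate_shared_triangles(
    net_normal: SignalingNetwork,
    net_tumor: SignalingNetwork,
    hubs: frozenset[str] | GeneSet,
) -> list[TriangleRecord]:
    """All hub-anchored triangles whose three links exist in both networks.

    A triangle with hubs at two (or three) corners yields one record per
    hub role.  Records are returned in deterministic sorted order.
    """
    hub_set = hubs.symbols if isinstance(hubs, GeneSet) else hubs
    gn, gt = net_normal.graph, net_tumor.graph
    common_nodes = set(gn) & set(gt)

    def common_edge(a: str, b: str) -> bool:
        return gn.has_edge(a, b) and gt.has_edge(a, b)

    records: list[TriangleRecord] = []
    for hub in sorted(hub_set & common_nodes):
        nbrs = sorted(
            n for n in gn[hub] if n in common_nodes and common_edge(hub, n)
        )
        for i, n1 in enumerate(nbrs):
            for n2 in nbrs[i + 1:]:
                if not common_edge(n1, n2):
                    continue
                links = [
                    normalize_link(hub, n1),
                    normalize_link(hub, n2),
                    normalize_link(n1, n2),
                ]
                records.append(
                    TriangleRecord(
                        hub=hub,
                        n1=n1,
                        n2=n2,
                        rho_normal={l: gn.edges[l]["rho"] for l in links},
                        rho_tumor={l: gt.edges[l]["rho"] for l in links},
                    )
                )
    return records


def count_integration_motifs(
    triangles: list[TriangleRecord], bounds: tuple[float, float] = (0.3, 0.5)
) -> tuple[int, int]:
    """Per cohort: triangles whose three links are all in the high category."""
    counts = []
    for cohort in ("normal", "tumor"):
        n = 0
        for t in triangles:
            cats = t.categories(cohort, bounds)
            if all(c == "high" for c in cats.values()):
                n += 1
        counts.append(n)
    return counts[0], counts[1]


def count_maintenance_motifs(
    triangles: list[TriangleRecord], bounds: tuple[float, float] = (0.3, 0.5)
) -> tuple[int, int]:
    """Hub detached in one cohort, vicinity regulation maintained.

    The tumor count holds triangles whose hub links are high in normal and
    uncorrelated in tumor (hub detached *in the tumor*) with the
    neighbor-neighbor category unchanged; the normal count is the mirror.
    """
    normal = tumor = 0
    for t in triangles:
        cn = t.categories("normal", bounds)
        ct = t.categories("tumor", bounds)
        h1, h2 = t.hub_links
        nn = t.neighbor_link
        if cn[nn] != ct[nn]:
            continue
        if cn[h1] == cn[h2] == "high" and ct[h1] == ct[h2] == "none":
            tumor += 1
        elif ct[h1] == ct[h2] == "high" and cn[h1] == cn[h2] == "none":
            normal += 1
    return normal, tumor


def count_comparative_motifs(
    paths_normal: PathwaySet, paths_tumor: PathwaySet
) -> tuple[int, int]:
    """Receptor pairs on a common TF sharing a link in exactly one cohort.

    For every TF and unordered receptor pair {R1, R2} whose four pathways
    (R1->TF and R2->TF in both cohorts) all exist: the normal count rises
    when the two normal pathways share >= 1 link while the two tumor
    pathways share none, and vice versa for the tumor count.
    """
    def by_tf(paths: PathwaySet) -> dict[str, dict[str, frozenset]]:
        table: dict[str, dict[str, frozenset]] = {}
        for p in paths:
            table.setdefault(p.tf, {})[p.receptor] = p.links
        return table

    tn, tt = by_tf(paths_normal), by_tf(paths_tumor)
    normal = tumor = 0
    for tf in sorted(set(tn) & set(tt)):
        receptors = sorted(set(tn[tf]) & set(tt[tf]))
        for i, r1 in enumerate(receptors):
            n1, t1 = tn[tf][r1], tt[tf][r1]
            for r2 in receptors[i + 1:]:
                share_n = not n1.isdisjoint(tn[tf][r2])
                share_t = not t1.isdisjoint(tt[tf][r2])
                if share_n and not share_t:
                    normal += 1
                elif share_t and not share_n:
                    tumor += 1
    return normal, tumor
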