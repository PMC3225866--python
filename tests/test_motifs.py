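from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from corsignet import motifs as mf
from corsignet.features import FrequencyTable
from corsignet.io import GeneSet
from corsignet.pathways import (
    Pathway,
    PathwaySet,
    SignalingNetwork,
    build_signaling_network,
    extract_pathways,
)

from .helpers import brute_force_comparative, brute_force_triangles


def _freq_table(node_freq):
    return FrequencyTable(link_freq={}, node_freq=node_freq, pathway_count=1)


def _signet(edge_rhos: dict[tuple[str, str], float]) -> SignalingNetwork:
    g = nx.Graph()
    for (a, b), rho in edge_rhos.items():
        g.add_edge(a, b, rho=rho, distance=1 - abs(rho))
    return SignalingNetwork(
        graph=g, pathways=PathwaySet({}), link_freq={}, node_freq={},
        fraction_links_used=1.0, fraction_nodes_used=1.0,
    )


def _triangle(rho_n, rho_t, hub="H", n1="a", n2="b"):
    links = [tuple(sorted((hub, n1))), tuple(sorted((hub, n2))), tuple(sorted((n1, n2)))]
    return mf.TriangleRecord(
        hub=hub, n1=n1, n2=n2,
        rho_normal=dict(zip(links, rho_n)),
        rho_tumor=dict(zip(links, rho_t)),
    )


class TestSelectCancerHubs:
    def test_identical_top_k_counted_once(self):
        fn = _freq_table({"a": 10, "b": 9, "c": 1})
        ft = _freq_table({"a": 8, "b": 7, "c": 2})
        hubs = mf.select_cancer_hubs(
            fn, ft, GeneSet(role="cancer_mutated", symbols=frozenset("abc")), k=2
        )
        assert hubs == frozenset({"a", "b"})

    def test_disjoint_top_k_gives_two_k(self):
        fn = _freq_table({"a": 10, "b": 9, "c": 1, "d": 1})
        ft = _freq_table({"a": 1, "b": 1, "c": 10, "d": 9})
        hubs = mf.select_cancer_hubs(
            fn, ft, GeneSet(role="cancer_mutated", symbols=frozenset("abcd")), k=2
        )
        assert hubs == frozenset({"a", "b", "c", "d"})

    def test_hand_ranked_oracle_with_ties(self):
        # cancer genes only; tie at frequency 5 broken lexicographically
        fn = _freq_table({"x": 5, "y": 5, "z": 3, "w": 99})
        ft = _freq_table({"x": 1, "y": 2, "z": 9, "w": 99})
        cancer = GeneSet(role="cancer_mutated", symbols=frozenset({"x", "y", "z"}))
        hubs = mf.select_cancer_hubs(fn, ft, cancer, k=2)
        # normal ranks x before y (tie, lexicographic), tumor picks z, y
        assert hubs == frozenset({"x", "y", "z"})

    def test_empty_intersection_warns_and_returns_empty(self, caplog):
        fn, ft = _freq_table({"a": 1}), _freq_table({"a": 1})
        cancer = GeneSet(role="cancer_mutated", symbols=frozenset({"q"}))
        with caplog.at_level("WARNING"):
            assert mf.select_cancer_hubs(fn, ft, cancer, k=5) == frozenset()

    def test_none_disables_mutation_filter(self):
        fn, ft = _freq_table({"a": 2, "b": 1}), _freq_table({"a": 1, "b": 2})
        assert mf.select_cancer_hubs(fn, ft, None, k=1) == frozenset({"a", "b"})


class TestEnumerateSharedTriangles:
    def test_triangle_in_both_networks_yields_one_record(self):
        rhos = {("H", "a"): 0.8, ("H", "b"): 0.7, ("a", "b"): 0.6}
        records = mf.enumerate_shared_triangles(
            _signet(rhos), _signet(rhos), frozenset({"H"})
        )
        assert len(records) == 1
        assert records[0].hub == "H"

    def test_link_pruned_from_one_cohort_excludes_triangle(self):
        rhos = {("H", "a"): 0.8, ("H", "b"): 0.7, ("a", "b"): 0.6}
        tumor = {("H", "a"): 0.8, ("H", "b"): 0.7}  # a-b pruned in tumor
        records = mf.enumerate_shared_triangles(
            _signet(rhos), _signet(tumor), frozenset({"H"})
        )
        assert records == []

    def test_two_hub_corners_give_two_records(self):
        rhos = {("H1", "H2"): 0.8, ("H1", "c"): 0.7, ("H2", "c"): 0.6}
        records = mf.enumerate_shared_triangles(
            _signet(rhos), _signet(rhos), frozenset({"H1", "H2"})
        )
        assert [(r.hub) for r in records] == ["H1", "H2"]

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            gn = nx.gnp_random_graph(40, 0.12, seed=int(rng.integers(1 << 30)))
            gt = nx.gnp_random_graph(40, 0.12, seed=int(rng.integers(1 << 30)))
            for g in (gn, gt):
                for a, b in g.edges:
                    g.edges[a, b]["rho"] = float(rng.uniform(-1, 1))
            sn = _signet({e: gn.edges[e]["rho"] for e in gn.edges})
            st_ = _signet({e: gt.edges[e]["rho"] for e in gt.edges})
            hubs = frozenset(rng.choice(40, size=6, replace=False).tolist())
            got = mf.enumerate_shared_triangles(sn, st_, hubs)
            expected = brute_force_triangles(sn.graph, st_.graph, hubs)
            assert sorted((r.hub, r.n1, r.n2) for r in got) == sorted(expected)


class TestIntegrationMotif:
    @pytest.mark.parametrize(
        "rho_n, rho_t, expected",
        [
            ((0.8, 0.7, 0.6), (0.8, 0.1, 0.6), (1, 0)),
            ((0.8, 0.7, 0.4), (0.8, 0.7, 0.4), (0, 0)),  # n1-n2 only low
            ((0.8, 0.7, 0.6), (0.8, 0.7, 0.6), (1, 1)),
        ],
    )
    def test_worked_examples(self, rho_n, rho_t, expected):
        assert mf.count_integration_motifs([_triangle(rho_n, rho_t)]) == expected

    def test_negative_rho_counts_via_absolute_value(self):
        assert mf.count_integration_motifs(
            [_triangle((-0.8, 0.7, -0.6), (0.1, 0.1, 0.1))]
        ) == (1, 0)


class TestMaintenanceMotif:
    @pytest.mark.parametrize(
        "rho_n, rho_t, expected",
        [
            # hub high->none, n1-n2 stays low: attributed to tumor
            ((0.8, 0.7, 0.4), (0.1, 0.2, 0.35), (0, 1)),
            # n1-n2 changes category: no motif
            ((0.8, 0.7, 0.4), (0.1, 0.2, 0.55), (0, 0)),
            # hub drops only to low: no motif
            ((0.8, 0.7, 0.4), (0.4, 0.4, 0.4), (0, 0)),
            # mirror image: attributed to normal
            ((0.1, 0.2, 0.35), (0.8, 0.7, 0.4), (1, 0)),
        ],
    )
    def test_worked_examples(self, rho_n, rho_t, expected):
        assert mf.count_maintenance_motifs([_triangle(rho_n, rho_t)]) == expected


class TestComparativeMotif:
    @staticmethod
    def _paths(seqs):
        return PathwaySet(
            {
                (s[0], s[-1]): Pathway(
                    receptor=s[0], tf=s[-1], nodes=tuple(s),
                    total_distance=float(len(s) - 1),
                )
                for s in seqs
            }
        )

    def test_shared_in_normal_only(self):
        pn = self._paths([("R1", "X", "T"), ("R2", "X", "T")])
        pt = self._paths([("R1", "A", "T"), ("R2", "B", "T")])
        assert mf.count_comparative_motifs(pn, pt) == (1, 0)

    def test_identical_sets_share_in_both(self):
        pn = self._paths([("R1", "X", "T"), ("R2", "X", "T")])
        assert mf.count_comparative_motifs(pn, pn) == (0, 0)

    def test_pair_missing_in_one_cohort_skipped(self):
        pn = self._paths([("R1", "X", "T"), ("R2", "X", "T")])
        pt = self._paths([("R1", "A", "T")])
        assert mf.count_comparative_motifs(pn, pt) == (0, 0)

    def test_shared_node_without_shared_link_does_not_count(self):
        pn = self._paths([("R1", "X", "T"), ("R2", "Y", "X", "T")])  # share X-T
        pt = self._paths([("R1", "X", "T1x", "T"), ("R2", "X", "T2x", "T")])
        # tumor pathways share node X but no link
        assert mf.count_comparative_motifs(pn, pt) == (1, 0)


class TestMotifProperties:
    @staticmethod
    def _random_instance(seed):
        rng = np.random.default_rng(seed)
        g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        nets = []
        for _ in range(2):
            h = g.copy()
            for a, b in h.edges:
                rho = float(rng.uniform(-1, 1))
                h.edges[a, b].update(rho=rho, distance=1 - abs(rho))
            nets.append(h)
        nodes = sorted(g.nodes)
        receptors = GeneSet(role="receptor", symbols=frozenset(nodes[:6]))
        tfs = GeneSet(role="transcription_factor", symbols=frozenset(nodes[-5:]))
        signets = [
            build_signaling_network(h, extract_pathways(h, receptors, tfs))
            for h in nets
        ]
        return signets

    @pytest.mark.parametrize("seed", [3, 4])
    def test_swapping_cohorts_swaps_counts(self, seed):
        sn, st_ = self._random_instance(seed)
        hubs = frozenset(sorted(set(sn.graph) & set(st_.graph))[:8])
        tri = mf.enumerate_shared_triangles(sn, st_, hubs)
        tri_swapped = mf.enumerate_shared_triangles(st_, sn, hubs)
        assert mf.count_integration_motifs(tri) == tuple(
            reversed(mf.count_integration_motifs(tri_swapped))
        )
        assert mf.count_maintenance_motifs(tri) == tuple(
            reversed(mf.count_maintenance_motifs(tri_swapped))
        )
        assert mf.count_comparative_motifs(sn.pathways, st_.pathways) == tuple(
            reversed(mf.count_comparative_motifs(st_.pathways, sn.pathways))
        )

    @pytest.mark.parametrize("seed", [7, 8])
    def test_comparative_counter_matches_brute_force(self, seed):
        sn, st_ = self._random_instance(seed)
        assert mf.count_comparative_motifs(
            sn.pathways, st_.pathways
        ) == brute_force_comparative(sn.pathways, st_.pathways)

    def test_integration_bounded_by_triangle_count(self):
        sn, st_ = self._random_instance(9)
        hubs = frozenset(set(sn.graph) & set(st_.graph))
        tri = mf.enumerate_shared_triangles(sn, st_, hubs)
        n, t = mf.count_integration_motifs(tri)
        assert n + t <= 2 * len(tri)
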