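"""Signal clustering and graph assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from svgraph.graph_build import (
    GraphParams,
    LinkType,
    SignalGraph,
    build_graph,
    cluster_breakpoint_signals,
    cluster_discordant_signals,
    collect_split_junctions,
    discordant_cluster_distance,
)
from svgraph.signals import InsertSizeProfile, Signal, SignalKind

from conftest import build_graph_from_spec

FLAT_COVERAGE = lambda contig, pos: 30.0


def clip(pos, read_id, kind=SignalKind.CLIP_RIGHT, contig="chr1"):
    return Signal(kind, contig, pos, read_id, 60)


def arp(pos, mate_pos, read_id, kind=SignalKind.ARP_LARGE_INSERT, contig="chr1"):
    return Signal(kind, contig, pos, read_id, 60, contig, mate_pos)


class TestClipClustering:
    def test_merge_within_window(self):
        sigs = [clip(5000, "a/1"), clip(5001, "b/1"), clip(5000, "c/1")]
        nodes = cluster_breakpoint_signals(sigs, FLAT_COVERAGE,
                                           GraphParams(clip_merge_window=5))
        assert len(nodes) == 1
        assert len(nodes[0].read_ids) == 3
        assert (nodes[0].start, nodes[0].end) == (5000, 5002)

    def test_weight_filter(self):
        sigs = [clip(5000, "a/1", SignalKind.CLIP_LEFT)]
        assert cluster_breakpoint_signals(
            sigs, FLAT_COVERAGE, GraphParams(min_weight=2)) == []

    def test_weight_coverage_ratio_filter(self):
        sigs = [clip(5000, f"r{i}/1") for i in range(3)]
        nodes = cluster_breakpoint_signals(
            sigs, lambda c, p: 60.0, GraphParams(min_weight_ratio=0.1))
        assert nodes == []  # 3/60 = 0.05 < 0.1
        nodes = cluster_breakpoint_signals(
            sigs, lambda c, p: 20.0, GraphParams(min_weight_ratio=0.1))
        assert len(nodes) == 1

    def test_kinds_never_merge(self):
        sigs = sorted(
            [clip(5000, "a/1"), clip(5000, "b/1"), clip(5001, "e/1"),
             clip(5001, "c/1", SignalKind.CLIP_LEFT),
             clip(5002, "d/1", SignalKind.CLIP_LEFT),
             clip(5002, "f/1", SignalKind.CLIP_LEFT)],
            key=lambda s: s.pos,
        )
        nodes = cluster_breakpoint_signals(sigs, FLAT_COVERAGE, GraphParams())
        assert sorted(n.kind.value for n in nodes) == ["CLIP_LEFT", "CLIP_RIGHT"]


class TestClusterDistance:
    @pytest.mark.parametrize(
        "mean,rl,expected", [(500, 100, 300), (500, 250, 50), (300, 100, 100)]
    )
    def test_formula_with_floor(self, mean, rl, expected):
        prof = InsertSizeProfile(mean, 50.0, rl, 10_000)
        assert discordant_cluster_distance(prof) == expected


class TestDiscordantClustering:
    def test_six_pairs_two_nodes_one_record(self, default_profile):
        sigs = []
        for i in range(6):
            left, right = 10_000 + 20 * i, 15_000 + 23 * i
            sigs.append(arp(left, right, f"p{i}/1"))
            sigs.append(arp(right, left, f"p{i}/2"))
        nodes, recs = cluster_discordant_signals(sorted(sigs, key=lambda s: s.pos),
                                                 default_profile)
        assert len(nodes) == 2
        assert all(n.kind is SignalKind.ARP_LARGE_INSERT for n in nodes)
        assert [len(n.read_ids) for n in nodes] == [6, 6]
        assert len(recs) == 1 and recs[0].rp == 6

    def test_left_gap_beyond_distance_splits(self, default_profile):
        # clustering distance is 300; left ends 400 apart
        sigs = [arp(10_000, 15_000, "p0/1"), arp(15_000, 10_000, "p0/2"),
                arp(10_400, 15_050, "p1/1"), arp(15_050, 10_400, "p1/2")]
        nodes, recs = cluster_discordant_signals(
            sorted(sigs, key=lambda s: s.pos), default_profile,
            GraphParams(min_pair_support=1))
        lefts = [n for n in nodes if n.start < 12_000]
        assert len(lefts) == 2
        assert len(recs) == 2

    def test_isolated_pair_filtered(self, default_profile):
        sigs = [arp(10_000, 15_000, "p0/1"), arp(15_000, 10_000, "p0/2")]
        nodes, recs = cluster_discordant_signals(sigs, default_profile,
                                                 GraphParams(min_pair_support=2))
        assert nodes == [] and recs == []

    def test_low_support_vs_coverage_filtered(self, default_profile):
        sigs = []
        for i in range(2):
            sigs.append(arp(10_000 + i, 15_000 + i, f"p{i}/1"))
            sigs.append(arp(15_000 + i, 10_000 + i, f"p{i}/2"))
        nodes, _ = cluster_discordant_signals(
            sorted(sigs, key=lambda s: s.pos), default_profile,
            GraphParams(min_weight_ratio=0.1), coverage_fn=lambda c, p: 30.0)
        assert nodes == []  # 2/30 < 0.1
        nodes, _ = cluster_discordant_signals(
            sorted(sigs, key=lambda s: s.pos), default_profile,
            GraphParams(min_weight_ratio=0.1), coverage_fn=lambda c, p: 15.0)
        assert len(nodes) == 2

    @given(n_pairs=st.integers(1, 20), seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_clustering_never_inflates_support(self, n_pairs, seed):
        import numpy as np

        default_profile = InsertSizeProfile(500.0, 50.0, 100, 10_000)
        rng = np.random.default_rng(seed)
        sigs = []
        for i in range(n_pairs):
            left = int(rng.integers(0, 50_000))
            right = left + int(rng.integers(300, 5000))
            sigs.append(arp(left, right, f"p{i}/1"))
            sigs.append(arp(right, left, f"p{i}/2"))
        nodes, recs = cluster_discordant_signals(
            sorted(sigs, key=lambda s: s.pos), default_profile,
            GraphParams(min_pair_support=1))
        assert sum(len(n.read_ids) for n in nodes) <= len(sigs)
        for r in recs:
            assert r.rp <= n_pairs


class TestBuildGraph:
    def test_link_type_mapping_and_edges(self, default_profile):
        sigs = []
        for i in range(4):
            sigs.append(arp(10_000 + i, 15_000 + i, f"p{i}/1", SignalKind.ARP_RF))
            sigs.append(arp(15_000 + i, 10_000 + i, f"p{i}/2", SignalKind.ARP_RF))
        nodes, recs = cluster_discordant_signals(
            sorted(sigs, key=lambda s: s.pos), default_profile)
        graph = build_graph(nodes, recs, {})
        assert len(graph.nodes) == 2
        assert len(graph.epe_edges) == 1
        e = graph.epe_edges[0]
        assert e.link_type is LinkType.DUP and e.rp == 4
        # rp never exceeds endpoint weights
        assert e.rp <= min(graph.node(e.node_i).weight, graph.node(e.node_j).weight)

    def test_adjacent_edge_distance(self):
        g = build_graph_from_spec(
            [(SignalKind.CLIP_RIGHT, 900, 1000), (SignalKind.CLIP_LEFT, 1800, 1900)],
            [],
        )
        assert len(g.eae_edges) == 1
        assert g.eae_edges[0].dist == 800

    def test_single_node_graph_has_no_edges(self):
        g = build_graph_from_spec([(SignalKind.SPLIT, 1000)], [])
        assert g.epe_edges == [] and g.eae_edges == []

    def test_eae_edges_form_per_contig_path(self):
        g = build_graph_from_spec(
            [(SignalKind.SPLIT, 100), (SignalKind.SPLIT, 900),
             (SignalKind.CLIP_LEFT, 5000),
             (SignalKind.SPLIT, 100, 101, "chr2"), (SignalKind.SPLIT, 700, 701, "chr2")],
            [],
        )
        by_contig = {}
        for n in g.nodes:
            by_contig[n.contig] = by_contig.get(n.contig, 0) + 1
        assert len(g.eae_edges) == sum(c - 1 for c in by_contig.values())

    def test_split_junction_edges(self, default_profile):
        sigs = [
            Signal(SignalKind.SPLIT, "chr1", 5000, f"s{i}/1", 60) for i in range(3)
        ] + [
            Signal(SignalKind.SPLIT, "chr1", 9000, f"s{i}/1", 60) for i in range(3)
        ]
        nodes = cluster_breakpoint_signals(sigs, FLAT_COVERAGE, GraphParams())
        junctions = collect_split_junctions(sigs)
        graph = build_graph(nodes, [], junctions)
        assert len(graph.epe_edges) == 1
        assert graph.epe_edges[0].link_type is LinkType.SPLIT
        assert graph.epe_edges[0].rp == 3


class TestSerialization:
    def test_json_round_trip(self, toy_subgraph_graph, tmp_path):
        p = tmp_path / "graph.json"
        toy_subgraph_graph.to_json(str(p))
        back = SignalGraph.from_json(str(p))
        assert back.to_dict() == toy_subgraph_graph.to_dict()

    def test_graphml_round_trip(self, toy_subgraph_graph, tmp_path):
        p = tmp_path / "graph.graphml"
        toy_subgraph_graph.to_graphml(str(p))
        back = SignalGraph.from_graphml(str(p))
        assert back.to_dict() == toy_subgraph_graph.to_dict()

    def test_construction_is_permutation_invariant(self):
        specs = [(SignalKind.CLIP_RIGHT, 1000), (SignalKind.SPLIT, 400),
                 (SignalKind.ARP_FF, 2500), (SignalKind.CLIP_LEFT, 1000)]
        g1 = build_graph_from_spec(specs, [])
        g2 = build_graph_from_spec(list(reversed(specs)), [])
        assert [n.start for n in g1.nodes] == [n.start for n in g2.nodes]
        assert [n.kind for n in g1.nodes] == [n.kind for n in g2.nodes]
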