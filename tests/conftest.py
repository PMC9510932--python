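"""Shared fixtures: in-memory alignment records, toy graphs, small benchmarks."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from svgraph.graph_build import LinkType, PairedEdge, SignalGraph, SignalNode
from svgraph.signals import InsertSizeProfile, SignalKind
from svgraph.sim_forge import SimConfig, simulate_dataset

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000_000}]}
)


def make_record(
    name="r1",
    pos=1000,
    cigar=((0, 100),),
    flag_reverse=False,
    mate_pos=None,
    mate_reverse=True,
    tlen=500,
    mapq=60,
    read2=False,
    proper=True,
    paired=True,
    sa=None,
    supplementary=False,
    secondary=False,
    unmapped=False,
):
    """Construct an in-memory alignment record for classifier tests."""
    rec = pysam.AlignedSegment(HEADER)
    rec.query_name = name
    qlen = sum(ln for op, ln in cigar if op in (0, 1, 4))
    rec.query_sequence = "A" * qlen
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = list(cigar)
    rec.is_paired = paired
    rec.is_read2 = read2
    rec.is_read1 = paired and not read2
    rec.is_reverse = flag_reverse
    rec.is_proper_pair = proper
    rec.is_supplementary = supplementary
    rec.is_secondary = secondary
    rec.is_unmapped = unmapped
    if paired:
        rec.next_reference_id = 0
        if mate_pos is None:  # FR-consistent mate: fragment end minus one read
            mate_pos = pos + abs(tlen) - 100
        rec.next_reference_start = mate_pos
        rec.mate_is_reverse = mate_reverse
        rec.template_length = tlen
    if sa:
        rec.set_tag("SA", sa, value_type="Z")
    return rec


def make_node(node_id, kind, start, end=None, contig="chr1", weight=3):
    if end is None:
        end = start + 1
    reads = frozenset(f"n{node_id}_r{i}" for i in range(weight))
    return SignalNode(node_id, kind, contig, start, end, weight, reads)


def build_graph_from_spec(node_specs, epe_specs):
    """node_specs: (kind, start[, end]); epe_specs: (i, j, rp, link_type)."""
    nodes = []
    for i, spec in enumerate(node_specs):
        kind, start = spec[0], spec[1]
        end = spec[2] if len(spec) > 2 else start + 1
        contig = spec[3] if len(spec) > 3 else "chr1"
        nodes.append(make_node(i, kind, start, end, contig))
    epe = [PairedEdge(i, j, rp, lt) for i, j, rp, lt in epe_specs]
    return SignalGraph.from_nodes(nodes, epe)


@pytest.fixture
def default_profile():
    return InsertSizeProfile(mean_insert=500.0, sd_insert=50.0,
                             read_length=100, sample_size=10_000)


@pytest.fixture
def toy_subgraph_graph():
    """Four chained nodes of distinct kinds with two DEL paired edges,
    plus two distant, unconnected nodes that growth must not absorb."""
    return build_graph_from_spec(
        [
            (SignalKind.CLIP_RIGHT, 1000),        # A
            (SignalKind.ARP_LARGE_INSERT, 1300),  # C
            (SignalKind.ARP_FF, 1700),            # B
            (SignalKind.CLIP_LEFT, 2100),         # D
            (SignalKind.SPLIT, 50_000),           # E, far away
            (SignalKind.CLIP_RIGHT, 90_000),      # F, far away
        ],
        [(0, 2, 4, LinkType.DEL), (1, 3, 5, LinkType.DEL)],
    )


@pytest.fixture(scope="session")
def small_het_dataset(tmp_path_factory):
    """300 kb reference with 8 heterozygous reported-catalog CSVs at 30x."""
    out = tmp_path_factory.mktemp("sim_small_het")
    cfg = SimConfig(genome_length=300_000, n_events=8, coverage=30,
                    seed=11, zygosity="het")
    return simulate_dataset(cfg, str(out))
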