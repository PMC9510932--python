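"""End-to-end caller: BAM -> signals -> graph -> pattern growth -> calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pysam

from .calls import CsvCall, calls_from_subgraphs, filter_csv
from .evaluation import Interval
from .graph_build import (
    GraphParams,
    SignalGraph,
    build_graph,
    cluster_breakpoint_signals,
    cluster_discordant_signals,
    collect_split_junctions,
)
from .growth import GrowthParams, find_maximal_subgraphs
from .signals import (
    InsertSizeProfile,
    SignalParams,
    estimate_insert_profile,
    extract_signals,
)

logger = logging.getLogger(__name__)

__all__ = ["CallerResult", "estimate_profile_from_bam", "run_caller",
           "event_intervals", "prediction_intervals"]


@dataclass
class CallerResult:
    calls: list[CsvCall]
    graph: SignalGraph
    profile: InsertSizeProfile
    growth_params: GrowthParams


def estimate_profile_from_bam(
    bam_path: str, min_sample: int = 1000, target_sample: int = 20_000
) -> InsertSizeProfile:
    """Profile the library from the first ``target_sample`` proper pairs."""

    def stream():
        seen = 0
        with pysam.AlignmentFile(bam_path, "rb") as bam:
            for rec in bam.fetch():
                yield rec
                if rec.is_proper_pair and rec.template_length > 0:
                    seen += 1
                    if seen >= target_sample:
                        return

    return estimate_insert_profile(stream(), min_sample=min_sample)


def run_caller(
    bam_path: str,
    signal_params: SignalParams = SignalParams(),
    graph_params: GraphParams = GraphParams(),
    min_dist: Optional[int] = None,
    min_freq: int = 1,
    min_link_types: int = 1,
    region: Optional[tuple[str, int, int]] = None,
    profile: Optional[InsertSizeProfile] = None,
) -> CallerResult:
    """Run the full discovery pipeline on a coordinate-sorted indexed BAM.

    ``min_dist`` defaults to max(2 x mean insert, 1000) bp.  Calls are
    filtered to at least ``min_link_types`` edge connection types
    (default 1, i.e. the full callset).
    """
    if profile is None:
        profile = estimate_profile_from_bam(bam_path)
    logger.info(
        "insert profile: mean=%.1f sd=%.1f read_length=%d (n=%d)",
        profile.mean_insert, profile.sd_insert, profile.read_length,
        profile.sample_size,
    )
    signals = extract_signals(bam_path, profile, signal_params, region)
    logger.info("extracted %d signals", len(signals))

    with pysam.AlignmentFile(bam_path, "rb") as bam:

        def coverage_fn(contig: str, pos: int) -> float:
            return bam.count(
                contig, pos, pos + 1,
                read_callback=lambda r: not (
                    r.is_secondary or r.is_supplementary or r.is_duplicate
                ),
            )

        clip_nodes = cluster_breakpoint_signals(signals, coverage_fn, graph_params)
        arp_nodes, pairing = cluster_discordant_signals(
            signals, profile, graph_params, coverage_fn
        )
    splits = collect_split_junctions(signals)
    graph = build_graph(clip_nodes + arp_nodes, pairing, splits, graph_params)
    logger.info(
        "graph: %d nodes, %d paired edges, %d adjacent edges",
        len(graph.nodes), len(graph.epe_edges), len(graph.eae_edges),
    )

    if min_dist is None:
        min_dist = max(int(round(2 * profile.mean_insert)), 1000)
    growth_params = GrowthParams(min_freq=min_freq, min_dist=min_dist)
    subgraphs = find_maximal_subgraphs(graph, growth_params)
    calls = filter_csv(calls_from_subgraphs(subgraphs, graph), min_link_types)
    logger.info("%d maximal subgraphs -> %d calls", len(subgraphs), len(calls))
    return CallerResult(calls, graph, profile, growth_params)


def event_intervals(calls: Sequence[CsvCall]) -> list[Interval]:
    """One interval per call: the event boundary."""
    return [(c.contig, c.start, c.end) for c in calls]


def prediction_intervals(calls: Sequence[CsvCall]) -> list[Interval]:
    """Event boundaries plus per-paired-edge junction intervals."""
    from .calls import junction_intervals

    out: list[Interval] = []
    for c in calls:
        out.append((c.contig, c.start, c.end))
        out.extend(junction_intervals(c))
    return sorted(set(out))
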