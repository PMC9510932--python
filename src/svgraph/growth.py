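"""Maximal-subgraph detection by pattern growth.

A candidate complex-SV site is a maximal subgraph of the signal graph.
Growth starts from a single seed node and repeatedly appends one node in
increasing position order: either the immediate reference successor of the
current frontier when the genomic gap is below ``min_dist`` (adjacent-edge
extension), or any later node connected by a paired edge to a node already
in the subgraph (backtracking over the members, last to first).  A
subgraph that cannot be extended is a growth leaf; the output is the set
of leaves that are not node-subsets of another leaf.

Seeding follows the seed-and-extension strategy: every node of every
sufficiently frequent type seeds a growth on a per-type projected index.
Seeds already absorbed by an earlier growth are skipped — any subgraph
grown from such a seed is necessarily contained in a leaf of the earlier
growth, so the maximal set is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

from .graph_build import AdjacentEdge, PairedEdge, SignalGraph, SignalNode

__all__ = ["GrowthParams", "Subgraph", "node_in_range",
           "multi_loc_pattern_growth", "find_maximal_subgraphs"]


@dataclass(frozen=True)
class GrowthParams:
    """Pattern-growth parameters.

    min_freq
        Minimum type frequency for a node to participate; 1 by default so
        no rare subgraph is missed.
    min_dist
        Maximum genomic gap (bp) for extension along adjacent edges;
        paired-edge extensions are not distance-constrained.
    max_steps_per_seed
        Safety ceiling on extension attempts explored from one seed.
    """

    min_freq: int = 1
    min_dist: int = 1000
    max_steps_per_seed: int = 100_000

    def __post_init__(self) -> None:
        if self.min_freq < 1:
            raise ValueError("min_freq must be >= 1")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")


@dataclass(frozen=True)
class Subgraph:
    """An ordered (by position) set of node ids with its induced edges."""

    node_ids: tuple[int, ...]
    epe_edges: tuple[PairedEdge, ...]
    eae_edges: tuple[AdjacentEdge, ...]
    freq: int = 1

    def __len__(self) -> int:
        return len(self.node_ids)

    def node_set(self) -> frozenset[int]:
        return frozenset(self.node_ids)


def _gap(last: SignalNode, v: SignalNode) -> float:
    if last.contig != v.contig:
        return float("inf")
    return max(0, v.start - last.end)


def _accepts(
    g: Sequence[int], v: int, graph: SignalGraph, params: GrowthParams
) -> bool:
    """The growth rule, membership of ``v`` already excluded by the caller."""
    if graph.kind_freq[graph.node(v).kind] < params.min_freq:
        return False
    if _gap(graph.node(g[-1]), graph.node(v)) < params.min_dist:
        return True
    for member in reversed(g):
        if graph.has_epe(member, v):
            return True
    return False


def node_in_range(
    g: Sequence[int],
    v: int,
    graph: SignalGraph,
    params: GrowthParams,
) -> bool:
    """Can node ``v`` extend the growing subgraph ``g``?

    True when the gap to the last (rightmost) member is below
    ``min_dist``, or when a paired edge connects ``v`` to any member,
    scanned from the last added node back to the seed.
    """
    if v in g:
        raise ValueError(f"node {v} is already in the subgraph")
    return _accepts(g, v, graph, params)


def multi_loc_pattern_growth(
    seed: Sequence[int],
    graph: SignalGraph,
    params: GrowthParams,
    out: Optional[list[tuple[int, ...]]] = None,
    leaves_only: bool = True,
) -> list[tuple[int, ...]]:
    """Depth-first growth from ``seed``; returns grown node-id tuples.

    Candidates at each step are the immediate reference successor of the
    frontier plus the paired-edge neighbors of all members positioned
    after the frontier (the projected index, maintained incrementally).
    With ``leaves_only`` (default) only subgraphs that admit no further
    extension are recorded; otherwise every accepted intermediate is
    appended as well.  Deterministic: candidates are explored in
    canonical node order, i.e. (start, kind).
    """
    if out is None:
        out = []
    budget = params.max_steps_per_seed
    seed_list = list(seed)
    members = set(seed_list)
    epe_cand: set[int] = set()
    for m in seed_list:
        epe_cand.update(graph.epe_neighbors(m))
    stack: list[tuple[list[int], set[int], set[int]]] = [
        (seed_list, members, epe_cand)
    ]
    n_nodes = len(graph.nodes)
    while stack:
        g, members, epe_cand = stack.pop()
        while True:
            if len(g) > n_nodes:
                raise AssertionError("growth exceeded node count (cycle guard)")
            last = g[-1]
            cand: set[int] = set()
            succ = graph.successor(last)
            if succ is not None and succ.node_id not in members:
                cand.add(succ.node_id)
            for c in epe_cand:
                if c > last and c not in members:
                    cand.add(c)
            accepted = []
            for c in sorted(cand):
                if budget <= 0:
                    break
                budget -= 1
                if _accepts(g, c, graph, params):
                    accepted.append(c)
            if not accepted:
                if leaves_only:
                    out.append(tuple(g))
                break
            if len(accepted) == 1:
                # non-branching path: extend in place
                c = accepted[0]
                g.append(c)
                members.add(c)
                epe_cand.update(graph.epe_neighbors(c))
                if not leaves_only:
                    out.append(tuple(g))
                continue
            for c in reversed(accepted):
                g2 = g + [c]
                m2 = members | {c}
                e2 = epe_cand | set(graph.epe_neighbors(c))
                if not leaves_only:
                    out.append(tuple(g2))
                stack.append((g2, m2, e2))
            break
    return out


def find_maximal_subgraphs(
    graph: SignalGraph, params: GrowthParams
) -> list[Subgraph]:
    """Detect maximal subgraphs over the whole signal graph.

    Every node of a type with frequency >= ``min_freq`` seeds a growth;
    the accumulated growth leaves are reduced to subgraphs that are not a
    node-subset of another, sorted by leftmost position.  ``freq`` counts
    the genomic instances sharing the same node-type sequence.
    """
    if not graph.nodes:
        return []
    leaves: list[tuple[int, ...]] = []
    covered: set[int] = set()
    for node in graph.nodes:  # canonical position order
        if graph.kind_freq[node.kind] < params.min_freq:
            continue
        if node.node_id in covered:
            continue
        grown = multi_loc_pattern_growth([node.node_id], graph, params)
        for leaf in grown:
            covered.update(leaf)
        leaves.extend(grown)

    # maximality: drop node-subsets of another leaf
    unique = {frozenset(t): t for t in leaves}
    by_size = sorted(unique, key=len, reverse=True)
    kept: list[frozenset[int]] = []
    for s in by_size:
        if any(s < k for k in kept):
            continue
        kept.append(s)

    kind_seq_count: dict[tuple[str, ...], int] = {}
    results = []
    for s in kept:
        ids = tuple(sorted(s))
        kinds = tuple(graph.node(i).kind.value for i in ids)
        kind_seq_count[kinds] = kind_seq_count.get(kinds, 0) + 1
        results.append((ids, kinds))
    out = []
    for ids, kinds in results:
        members = set(ids)
        epe = tuple(
            e for e in graph.epe_edges if e.node_i in members and e.node_j in members
        )
        eae = tuple(
            e for e in graph.eae_edges if e.node_i in members and e.node_j in members
        )
        out.append(Subgraph(ids, epe, eae, freq=kind_seq_count[kinds]))
    out.sort(key=lambda sg: (graph.node(sg.node_ids[0]).contig,
                             graph.node(sg.node_ids[0]).start,
                             sg.node_ids))
    return out
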