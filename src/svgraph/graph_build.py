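"""Signal-graph construction.

Signals are clustered into weighted nodes and assembled into the signal
graph G = (V, E) with two edge families:

* paired edges (Epe) supported by discordant read-pairs or split reads
  that span two loci, typed by the rearrangement the supporting pairs
  imply (DEL / DUP / INV / INS / SPLIT);
* adjacent edges (Eae) induced by the reference genome between each pair
  of consecutive nodes on a contig, attributed with their genomic gap.

Each node is v = (type, [start, end), weight) where weight counts the
distinct supporting read ends.
"""

from __future__ import annotations

import enum
import json
import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .signals import ARP_KINDS, InsertSizeProfile, Signal, SignalKind

logger = logging.getLogger(__name__)

__all__ = [
    "LinkType",
    "GraphParams",
    "SignalNode",
    "PairedEdge",
    "AdjacentEdge",
    "PairingRecord",
    "SignalGraph",
    "cluster_breakpoint_signals",
    "discordant_cluster_distance",
    "cluster_discordant_signals",
    "collect_split_junctions",
    "build_graph",
]


class LinkType(enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    SPLIT = "SPLIT"


#: rearrangement implied by each discordant-pair kind
ARP_LINK_TYPE = {
    SignalKind.ARP_LARGE_INSERT: LinkType.DEL,
    SignalKind.ARP_SMALL_INSERT: LinkType.INS,
    SignalKind.ARP_RF: LinkType.DUP,
    SignalKind.ARP_FF: LinkType.INV,
    SignalKind.ARP_RR: LinkType.INV,
}

#: orientation-class node kinds whose Eae edges carry a variant type
EAE_KIND_LINK = {
    SignalKind.ARP_FF: LinkType.INV,
    SignalKind.ARP_RR: LinkType.INV,
    SignalKind.ARP_RF: LinkType.DUP,
}


@dataclass(frozen=True)
class GraphParams:
    """Clustering and filtering thresholds for graph construction."""

    clip_merge_window: int = 5
    min_weight: int = 2
    min_weight_ratio: float = 0.1
    min_pair_support: int = 2
    min_cluster_distance_floor: int = 50


@dataclass(frozen=True)
class SignalNode:
    node_id: int
    kind: SignalKind
    contig: str
    start: int
    end: int
    weight: int
    read_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("node start must be <= end")
        if self.weight < 1 or self.weight != len(self.read_ids):
            raise ValueError("node weight must equal |read_ids| >= 1")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PairedEdge:
    node_i: int
    node_j: int
    rp: int
    link_type: LinkType

    def __post_init__(self) -> None:
        if self.rp < 1:
            raise ValueError("paired edge support must be >= 1")


@dataclass(frozen=True)
class AdjacentEdge:
    node_i: int
    node_j: int
    dist: int

    def __post_init__(self) -> None:
        if self.dist < 0:
            raise ValueError("adjacent edge dist must be >= 0 (clamped)")


@dataclass
class PairingRecord:
    """Which left cluster pairs with which right cluster, and how often."""

    kind: SignalKind
    contig: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    pair_names: frozenset[str]

    @property
    def rp(self) -> int:
        return len(self.pair_names)


class SignalGraph:
    """Position-sorted nodes plus paired (Epe) and adjacent (Eae) edges.

    Nodes are canonically ordered by (contig, start, kind, end); node ids
    are their rank in that order, making construction deterministic and
    permutation-invariant.
    """

    def __init__(
        self,
        nodes: Sequence[SignalNode],
        epe_edges: Iterable[PairedEdge] = (),
        eae_edges: Optional[Iterable[AdjacentEdge]] = None,
    ) -> None:
        self.nodes: list[SignalNode] = list(nodes)
        self.epe_edges: list[PairedEdge] = sorted(
            epe_edges, key=lambda e: (e.node_i, e.node_j, e.link_type.value)
        )
        if eae_edges is None:
            eae = []
            for a, b in zip(self.nodes, self.nodes[1:]):
                if a.contig != b.contig:
                    continue
                eae.append(
                    AdjacentEdge(a.node_id, b.node_id, max(0, b.start - a.end))
                )
            self.eae_edges: list[AdjacentEdge] = eae
        else:
            self.eae_edges = list(eae_edges)
        self._epe_adj: dict[int, list[PairedEdge]] = defaultdict(list)
        self._epe_pairs: set[tuple[int, int]] = set()
        for e in self.epe_edges:
            self._epe_adj[e.node_i].append(e)
            self._epe_adj[e.node_j].append(e)
            self._epe_pairs.add((e.node_i, e.node_j))
        self.kind_freq: dict[SignalKind, int] = defaultdict(int)
        for n in self.nodes:
            self.kind_freq[n.kind] += 1

    @staticmethod
    def from_nodes(
        nodes: Iterable[SignalNode], epe_edges: Iterable[PairedEdge] = ()
    ) -> "SignalGraph":
        """Build a graph from bare nodes, renumbering ids canonically.

        ``epe_edges`` refer to the ids the input nodes carry; they are
        remapped onto the canonical numbering.
        """
        old = list(nodes)
        order = sorted(
            range(len(old)),
            key=lambda i: (old[i].contig, old[i].start, old[i].kind.value, old[i].end),
        )
        remap = {old[i].node_id: rank for rank, i in enumerate(order)}
        new_nodes = [
            SignalNode(
                rank,
                old[i].kind,
                old[i].contig,
                old[i].start,
                old[i].end,
                old[i].weight,
                old[i].read_ids,
            )
            for rank, i in enumerate(order)
        ]
        new_epe = []
        for e in epe_edges:
            a, b = remap[e.node_i], remap[e.node_j]
            if a > b:
                a, b = b, a
            new_epe.append(PairedEdge(a, b, e.rp, e.link_type))
        return SignalGraph(new_nodes, new_epe)

    # -- queries -------------------------------------------------------

    def node(self, node_id: int) -> SignalNode:
        return self.nodes[node_id]

    def successor(self, node_id: int) -> Optional[SignalNode]:
        """Immediate same-contig successor in position order."""
        if node_id + 1 < len(self.nodes):
            nxt = self.nodes[node_id + 1]
            if nxt.contig == self.nodes[node_id].contig:
                return nxt
        return None

    def epe_neighbors(self, node_id: int) -> list[int]:
        out = []
        for e in self._epe_adj.get(node_id, ()):
            out.append(e.node_j if e.node_i == node_id else e.node_i)
        return out

    def has_epe(self, a: int, b: int) -> bool:
        if a > b:
            a, b = b, a
        return (a, b) in self._epe_pairs

    def epe_between(self, a: int, b: int) -> list[PairedEdge]:
        if a > b:
            a, b = b, a
        return [e for e in self._epe_adj.get(a, ()) if (e.node_i, e.node_j) == (a, b)]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "kind": n.kind.value,
                    "contig": n.contig,
                    "start": n.start,
                    "end": n.end,
                    "weight": n.weight,
                    "read_ids": sorted(n.read_ids),
                }
                for n in self.nodes
            ],
            "epe_edges": [
                {
                    "node_i": e.node_i,
                    "node_j": e.node_j,
                    "rp": e.rp,
                    "link_type": e.link_type.value,
                }
                for e in self.epe_edges
            ],
            "eae_edges": [
                {"node_i": e.node_i, "node_j": e.node_j, "dist": e.dist}
                for e in self.eae_edges
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "SignalGraph":
        nodes = [
            SignalNode(
                x["node_id"],
                SignalKind(x["kind"]),
                x["contig"],
                x["start"],
                x["end"],
                x["weight"],
                frozenset(x["read_ids"]),
            )
            for x in d["nodes"]
        ]
        epe = [
            PairedEdge(x["node_i"], x["node_j"], x["rp"], LinkType(x["link_type"]))
            for x in d["epe_edges"]
        ]
        eae = [
            AdjacentEdge(x["node_i"], x["node_j"], x["dist"]) for x in d["eae_edges"]
        ]
        return SignalGraph(nodes, epe, eae)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_json(path: str) -> "SignalGraph":
        with open(path) as fh:
            return SignalGraph.from_dict(json.load(fh))

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(
                n.node_id,
                kind=n.kind.value,
                contig=n.contig,
                start=n.start,
                end=n.end,
                weight=n.weight,
                read_ids=",".join(sorted(n.read_ids)),
            )
        for e in self.epe_edges:
            g.add_edge(e.node_i, e.node_j, family="epe", rp=e.rp,
                       link_type=e.link_type.value)
        for e in self.eae_edges:
            g.add_edge(e.node_i, e.node_j, family="eae", dist=e.dist)
        nx.write_graphml(g, path)

    @staticmethod
    def from_graphml(path: str) -> "SignalGraph":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = []
        for nid, attr in g.nodes(data=True):
            nodes.append(
                SignalNode(
                    int(nid), SignalKind(attr["kind"]), attr["contig"],
                    int(attr["start"]), int(attr["end"]), int(attr["weight"]),
                    frozenset(attr["read_ids"].split(",")),
                )
            )
        nodes.sort(key=lambda n: n.node_id)
        epe, eae = [], []
        for a, b, attr in g.edges(data=True):
            i, j = sorted((int(a), int(b)))
            if attr["family"] == "epe":
                epe.append(PairedEdge(i, j, int(attr["rp"]),
                                      LinkType(attr["link_type"])))
            else:
                eae.append(AdjacentEdge(i, j, int(attr["dist"])))
        eae.sort(key=lambda e: e.node_i)
        return SignalGraph(nodes, epe, eae)


# ---------------------------------------------------------------------
# clustering


@dataclass
class _RawNode:
    kind: SignalKind
    contig: str
    start: int
    end: int
    read_ids: set[str]


def cluster_breakpoint_signals(
    signals: Iterable[Signal],
    coverage_fn: Callable[[str, int], float],
    params: GraphParams = GraphParams(),
) -> list[_RawNode]:
    """Cluster CLIP/SPLIT signals at (nearly) the same position.

    Same-kind signals within ``clip_merge_window`` bp merge into one node
    (single linkage); clusters failing the weight or weight/coverage
    filters are discarded.
    """
    groups: dict[tuple[str, SignalKind], list[Signal]] = defaultdict(list)
    for s in signals:
        if s.kind in ARP_KINDS:
            continue
        groups[(s.contig, s.kind)].append(s)

    out: list[_RawNode] = []
    for (contig, kind), sigs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        sigs.sort(key=lambda s: (s.pos, s.read_id))
        cluster: list[Signal] = []
        for s in sigs:
            if cluster and s.pos - cluster[-1].pos > params.clip_merge_window:
                out.extend(_finish_clip_cluster(cluster, contig, kind, coverage_fn, params))
                cluster = []
            cluster.append(s)
        if cluster:
            out.extend(_finish_clip_cluster(cluster, contig, kind, coverage_fn, params))
    out.sort(key=lambda n: (n.contig, n.start, n.kind.value))
    return out


def _finish_clip_cluster(cluster, contig, kind, coverage_fn, params):
    read_ids = {s.read_id for s in cluster}
    weight = len(read_ids)
    if weight < params.min_weight:
        return []
    start = min(s.pos for s in cluster)
    end = max(s.pos for s in cluster) + 1
    cov = coverage_fn(contig, (start + end) // 2)
    if cov > 0 and weight / cov < params.min_weight_ratio:
        return []
    return [_RawNode(kind, contig, start, end, read_ids)]


def discordant_cluster_distance(
    profile: InsertSizeProfile, params: GraphParams = GraphParams()
) -> int:
    """Clustering distance for discordant pairs.

    The estimated average insert size minus two-fold read length, floored
    so degenerate libraries (long reads, short inserts) still cluster.
    """
    return max(
        int(round(profile.mean_insert - 2 * profile.read_length)),
        params.min_cluster_distance_floor,
    )


def cluster_discordant_signals(
    signals: Iterable[Signal],
    profile: InsertSizeProfile,
    params: GraphParams = GraphParams(),
    coverage_fn: Optional[Callable[[str, int], float]] = None,
) -> tuple[list[_RawNode], list[PairingRecord]]:
    """Cluster discordant read-pairs per abnormal-alignment kind.

    Each read-pair contributes its left end to one node and its right end
    to another; single-linkage clustering with gap <= the discordant
    cluster distance is applied to left ends, then to right ends within
    each left cluster.  As a control against randomly occurring
    discordant alignments, clusters with fewer than ``min_pair_support``
    pairs are discarded, as are clusters whose support/coverage ratio is
    below ``min_weight_ratio`` (when ``coverage_fn`` is given; the larger
    of the two cluster-end coverages is used so clusters bordering
    deleted sequence are not penalized).
    """
    dist = discordant_cluster_distance(profile, params)
    # collapse the two per-end signals of a pair into (left, right) coords
    pairs: dict[tuple[str, SignalKind, str], list[Signal]] = defaultdict(list)
    for s in signals:
        if s.kind not in ARP_KINDS:
            continue
        pairs[(s.contig, s.kind, s.pair_name())].append(s)

    by_group: dict[tuple[str, SignalKind], list[tuple[int, int, str]]] = defaultdict(list)
    for (contig, kind, name), sigs in pairs.items():
        if len(sigs) >= 2:
            coords = sorted(s.pos for s in sigs)
            left, right = coords[0], coords[-1]
        else:
            s = sigs[0]
            if s.mate_pos is None:
                continue
            left, right = min(s.pos, s.mate_pos), max(s.pos, s.mate_pos)
        by_group[(contig, kind)].append((left, right, name))

    nodes: list[_RawNode] = []
    records: list[PairingRecord] = []
    for (contig, kind), items in sorted(
        by_group.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        items.sort()
        # single linkage on left ends
        left_clusters: list[list[tuple[int, int, str]]] = []
        for it in items:
            if left_clusters and it[0] - left_clusters[-1][-1][0] <= dist:
                left_clusters[-1].append(it)
            else:
                left_clusters.append([it])
        for lc in left_clusters:
            lc.sort(key=lambda t: (t[1], t[0], t[2]))
            sub: list[list[tuple[int, int, str]]] = []
            for it in lc:
                if sub and it[1] - sub[-1][-1][1] <= dist:
                    sub[-1].append(it)
                else:
                    sub.append([it])
            for cluster in sub:
                if len(cluster) < params.min_pair_support:
                    continue
                lefts = [c[0] for c in cluster]
                rights = [c[1] for c in cluster]
                if coverage_fn is not None:
                    cov = max(
                        coverage_fn(contig, (min(lefts) + max(lefts)) // 2),
                        coverage_fn(contig, (min(rights) + max(rights)) // 2),
                    )
                    if cov > 0 and len(cluster) / cov < params.min_weight_ratio:
                        continue
                names = frozenset(c[2] for c in cluster)
                ln = _RawNode(
                    kind, contig, min(lefts), max(lefts) + 1,
                    {f"{n}/L" for n in names},
                )
                rn = _RawNode(
                    kind, contig, min(rights), max(rights) + 1,
                    {f"{n}/R" for n in names},
                )
                nodes.append(ln)
                nodes.append(rn)
                records.append(
                    PairingRecord(
                        kind, contig,
                        (ln.start, ln.end), (rn.start, rn.end), names,
                    )
                )
    nodes.sort(key=lambda n: (n.contig, n.start, n.kind.value))
    return nodes, records


def collect_split_junctions(signals: Iterable[Signal]) -> dict[str, list[tuple[str, int]]]:
    """Group SPLIT signal coordinates by read end (junction records)."""
    rec: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for s in signals:
        if s.kind is SignalKind.SPLIT:
            rec[s.read_id].append((s.contig, s.pos))
    return {k: sorted(v) for k, v in rec.items() if len(v) >= 1}


def build_graph(
    raw_nodes: Sequence[_RawNode],
    pairing_records: Sequence[PairingRecord],
    split_junctions: Optional[dict[str, list[tuple[str, int]]]] = None,
    params: GraphParams = GraphParams(),
) -> SignalGraph:
    """Assemble the signal graph from clustered nodes.

    Epe edges come from discordant pairing records (link type mapped from
    the generating ARP kind) and from co-occurrence of SPLIT junctions on
    the same read; parallel edges of different link types between the same
    node pair are all retained.  Eae edges connect every consecutive
    same-contig node pair.
    """
    ordered = sorted(raw_nodes, key=lambda n: (n.contig, n.start, n.kind.value, n.end))
    nodes = [
        SignalNode(i, n.kind, n.contig, n.start, n.end, len(n.read_ids),
                   frozenset(n.read_ids))
        for i, n in enumerate(ordered)
    ]

    # locate a node from its defining span / a contained coordinate
    span_index: dict[tuple[str, SignalKind, int, int], int] = {}
    by_kind: dict[tuple[str, SignalKind], list[tuple[int, int, int]]] = defaultdict(list)
    for n in nodes:
        span_index[(n.contig, n.kind, n.start, n.end)] = n.node_id
        by_kind[(n.contig, n.kind)].append((n.start, n.end, n.node_id))
    for v in by_kind.values():
        v.sort()

    def find_split_node(contig: str, pos: int) -> Optional[int]:
        spans = by_kind.get((contig, SignalKind.SPLIT))
        if not spans:
            return None
        i = bisect_right(spans, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and spans[i][0] <= pos < spans[i][1]:
            return spans[i][2]
        return None

    edge_support: dict[tuple[int, int, LinkType], set[str]] = defaultdict(set)
    dangling = 0
    for pr in pairing_records:
        a = span_index.get((pr.contig, pr.kind, *pr.left_span))
        b = span_index.get((pr.contig, pr.kind, *pr.right_span))
        if a is None or b is None:
            dangling += 1
            continue
        if a == b:
            continue
        if a > b:
            a, b = b, a
        edge_support[(a, b, ARP_LINK_TYPE[pr.kind])].update(pr.pair_names)

    if split_junctions:
        for read_id, junctions in split_junctions.items():
            hit = []
            for contig, pos in junctions:
                nid = find_split_node(contig, pos)
                if nid is not None:
                    hit.append(nid)
            for a, b in {
                (min(x, y), max(x, y))
                for i, x in enumerate(hit)
                for y in hit[i + 1:]
                if x != y
            }:
                edge_support[(a, b, LinkType.SPLIT)].add(read_id)

    if dangling:
        logger.info("dropped %d dangling pairing records", dangling)

    epe = [
        PairedEdge(a, b, len(names), lt)
        for (a, b, lt), names in sorted(
            edge_support.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
        )
    ]
    return SignalGraph(nodes, epe)
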