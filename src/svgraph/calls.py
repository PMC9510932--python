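"""Converting maximal subgraphs into complex-SV calls.

A call's boundary is the leftmost node start and the rightmost node end of
its subgraph; its complexity score CXS is the number of distinct node
types multiplied by the number of induced paired (Epe) edges; its type
label is the sorted set of edge connection types (e.g. ``Del,Inv``).

Output is VCF 4.2 with symbolic ``<CSV>`` ALT plus two sidecars: a BED
(0-based half-open) holding the event intervals and the per-paired-edge
junction intervals for breakpoint-level evaluation, and a JSON document
with the full subgraph of every call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from .graph_build import (
    EAE_KIND_LINK,
    LinkType,
    PairedEdge,
    SignalGraph,
    SignalNode,
)
from .growth import Subgraph

__all__ = [
    "CsvCall",
    "call_from_subgraph",
    "calls_from_subgraphs",
    "filter_csv",
    "label_type",
    "junction_intervals",
    "write_calls",
    "read_calls_json",
]

_LINK_LABEL = {
    LinkType.DEL: "Del",
    LinkType.DUP: "Dup",
    LinkType.INV: "Inv",
    LinkType.INS: "Ins",
    LinkType.SPLIT: "Split",
}


@dataclass(frozen=True)
class CsvCall:
    contig: str
    start: int
    end: int
    cxs: int
    link_types: frozenset[LinkType]
    subgraph: Subgraph
    nodes: tuple[SignalNode, ...]
    n_node_types: int
    n_epe: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("call start must be < end")


def call_from_subgraph(g: Subgraph, graph: SignalGraph) -> CsvCall:
    """Derive boundary, CXS and link types from one maximal subgraph."""
    nodes = tuple(graph.node(i) for i in g.node_ids)
    start = min(n.start for n in nodes)
    end = max(n.end for n in nodes)
    kinds = {n.kind for n in nodes}
    n_epe = len(g.epe_edges)
    cxs = len(kinds) * n_epe
    link_types = {e.link_type for e in g.epe_edges}
    # an adjacent edge joining two orientation-class nodes of the same kind
    # carries that kind's variant type (e.g. an Eae edge of type Inv)
    for e in g.eae_edges:
        a, b = graph.node(e.node_i), graph.node(e.node_j)
        if a.kind == b.kind and a.kind in EAE_KIND_LINK:
            link_types.add(EAE_KIND_LINK[a.kind])
    if not link_types:
        # edgeless subgraph: fall back to the types the node kinds imply
        from .graph_build import ARP_LINK_TYPE

        link_types = {ARP_LINK_TYPE[k] for k in kinds if k in ARP_LINK_TYPE}
        if not link_types:
            link_types = {LinkType.SPLIT}
    return CsvCall(
        contig=nodes[0].contig,
        start=start,
        end=max(end, start + 1),
        cxs=cxs,
        link_types=frozenset(link_types),
        subgraph=g,
        nodes=nodes,
        n_node_types=len(kinds),
        n_epe=n_epe,
    )


def calls_from_subgraphs(
    subgraphs: Iterable[Subgraph], graph: SignalGraph
) -> list[CsvCall]:
    calls = [call_from_subgraph(g, graph) for g in subgraphs]
    calls.sort(key=lambda c: (c.contig, c.start, c.end))
    return calls


def filter_csv(calls: Sequence[CsvCall], min_link_types: int = 2) -> list[CsvCall]:
    """Retain calls with at least ``min_link_types`` edge connection types."""
    return [c for c in calls if len(c.link_types) >= min_link_types]


def label_type(call: CsvCall) -> str:
    """Canonical comma-joined sorted type label, e.g. ``"Del,Inv"``."""
    return ",".join(sorted(_LINK_LABEL[t] for t in call.link_types))


def junction_intervals(call: CsvCall) -> list[tuple[str, int, int]]:
    """Breakpoint-pair intervals, one per induced paired edge.

    For an edge between nodes i < j the junction is estimated at the
    breakpoint-proximal cluster edges: the end of node i's span and the
    start of node j's span.
    """
    by_id = {n.node_id: n for n in call.nodes}
    out = []
    for e in call.subgraph.epe_edges:
        a, b = by_id[e.node_i], by_id[e.node_j]
        lo, hi = a.end - 1, b.start
        if lo > hi:
            lo, hi = hi, lo
        out.append((call.contig, lo, max(hi, lo + 1)))
    return sorted(set(out))


# ---------------------------------------------------------------------
# serialization

_VCF_HEADER_LINES = [
    '##ALT=<ID=CSV,Description="Complex structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
    '##INFO=<ID=CXS,Number=1,Type=Integer,Description="Complexity score: distinct node types x paired edges">',
    '##INFO=<ID=LINKTYPES,Number=1,Type=String,Description="Edge connection types of the subgraph">',
    '##INFO=<ID=NNODES,Number=1,Type=Integer,Description="Nodes in the subgraph">',
    '##INFO=<ID=NEPE,Number=1,Type=Integer,Description="Paired edges in the subgraph">',
    '##INFO=<ID=NTYPES,Number=1,Type=Integer,Description="Distinct node types in the subgraph">',
]


def write_calls(
    calls: Sequence[CsvCall],
    vcf_path: str,
    bed_path: Optional[str] = None,
    json_path: Optional[str] = None,
    reference: Optional[str] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write calls as VCF 4.2 plus BED and JSON sidecars.

    VCF coordinates are 1-based inclusive; the BED sidecar is 0-based
    half-open and holds one ``event`` row per call plus one ``junction``
    row per paired edge.  ``reference`` (FASTA with .fai) supplies contig
    order/length and the REF base; ``contig_lengths`` may be given
    instead.
    """
    fasta = pysam.FastaFile(reference) if reference else None
    try:
        if fasta is not None:
            contigs = list(zip(fasta.references, fasta.lengths))
        elif contig_lengths:
            contigs = list(contig_lengths.items())
        else:
            maxend: dict[str, int] = {}
            for c in calls:
                maxend[c.contig] = max(maxend.get(c.contig, 0), c.end)
            contigs = sorted((name, end + 1) for name, end in maxend.items())
        rank = {name: i for i, (name, _) in enumerate(contigs)}
        ordered = sorted(calls, key=lambda c: (rank.get(c.contig, len(rank)), c.start))

        header = pysam.VariantHeader()
        header.add_line("##fileformat=VCFv4.2")
        for line in _VCF_HEADER_LINES:
            header.add_line(line)
        for name, length in contigs:
            header.contigs.add(name, length=length)

        with pysam.VariantFile(vcf_path, "w", header=header) as vcf:
            for i, c in enumerate(ordered):
                ref_base = "N"
                if fasta is not None:
                    ref_base = (fasta.fetch(c.contig, c.start, c.start + 1) or "N").upper()
                rec = vcf.new_record(
                    contig=c.contig,
                    start=c.start,
                    stop=c.end,
                    alleles=(ref_base, "<CSV>"),
                    id=f"csv_{i + 1}",
                )
                rec.info["CXS"] = c.cxs
                rec.info["LINKTYPES"] = label_type(c).replace(",", "|")
                rec.info["NNODES"] = len(c.nodes)
                rec.info["NEPE"] = c.n_epe
                rec.info["NTYPES"] = c.n_node_types
                vcf.write(rec)
    finally:
        if fasta is not None:
            fasta.close()

    if bed_path is not None:
        with open(bed_path, "w") as bed:
            for i, c in enumerate(ordered):
                bed.write(
                    f"{c.contig}\t{c.start}\t{c.end}\tevent_{i + 1};"
                    f"{label_type(c)};CXS={c.cxs}\t{c.cxs}\n"
                )
                for j, (contig, lo, hi) in enumerate(junction_intervals(c)):
                    bed.write(
                        f"{contig}\t{lo}\t{hi}\tjunction_{i + 1}.{j + 1}\t{c.cxs}\n"
                    )

    if json_path is not None:
        doc = [_call_to_dict(c) for c in ordered]
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _call_to_dict(c: CsvCall) -> dict:
    return {
        "contig": c.contig,
        "start": c.start,
        "end": c.end,
        "cxs": c.cxs,
        "label": label_type(c),
        "link_types": sorted(t.value for t in c.link_types),
        "n_node_types": c.n_node_types,
        "n_epe": c.n_epe,
        "subgraph": {
            "node_ids": list(c.subgraph.node_ids),
            "freq": c.subgraph.freq,
            "epe_edges": [
                {"node_i": e.node_i, "node_j": e.node_j, "rp": e.rp,
                 "link_type": e.link_type.value}
                for e in c.subgraph.epe_edges
            ],
            "eae_edges": [
                {"node_i": e.node_i, "node_j": e.node_j, "dist": e.dist}
                for e in c.subgraph.eae_edges
            ],
        },
        "nodes": [
            {"node_id": n.node_id, "kind": n.kind.value, "contig": n.contig,
             "start": n.start, "end": n.end, "weight": n.weight,
             "read_ids": sorted(n.read_ids)}
            for n in c.nodes
        ],
    }


def read_calls_json(json_path: str) -> list[CsvCall]:
    """Round-trip loader for the JSON sidecar."""
    from .graph_build import AdjacentEdge
    from .signals import SignalKind

    with open(json_path) as fh:
        doc = json.load(fh)
    calls = []
    for d in doc:
        nodes = tuple(
            SignalNode(x["node_id"], SignalKind(x["kind"]), x["contig"],
                       x["start"], x["end"], x["weight"], frozenset(x["read_ids"]))
            for x in d["nodes"]
        )
        sg = d["subgraph"]
        subgraph = Subgraph(
            tuple(sg["node_ids"]),
            tuple(PairedEdge(e["node_i"], e["node_j"], e["rp"],
                             LinkType(e["link_type"])) for e in sg["epe_edges"]),
            tuple(AdjacentEdge(e["node_i"], e["node_j"], e["dist"])
                  for e in sg["eae_edges"]),
            freq=sg["freq"],
        )
        calls.append(
            CsvCall(
                contig=d["contig"], start=d["start"], end=d["end"], cxs=d["cxs"],
                link_types=frozenset(LinkType(t) for t in d["link_types"]),
                subgraph=subgraph, nodes=nodes,
                n_node_types=d["n_node_types"], n_epe=d["n_epe"],
            )
        )
    return calls
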