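"""Independent brute-force oracle for maximal-subgraph growth.

Re-derives the growth rules naively: from every eligible seed, enumerate
*all* extension sequences (no projected index, no covered-seed skipping,
no leaf shortcut), collect every grown node set, and keep the sets not
strictly contained in another.  Intentionally exponential; only for tiny
graphs.
"""

from __future__ import annotations


def _gap(graph, a, b):
    na, nb = graph.node(a), graph.node(b)
    if na.contig != nb.contig:
        return float("inf")
    return max(0, nb.start - na.end)


def _accepts(graph, g, v, min_freq, min_dist):
    if graph.kind_freq[graph.node(v).kind] < min_freq:
        return False
    if _gap(graph, g[-1], v) < min_dist:
        return True
    return any(graph.has_epe(m, v) for m in g)


def _candidates(graph, g):
    last = g[-1]
    cand = set()
    nxt = graph.successor(last)
    if nxt is not None:
        cand.add(nxt.node_id)
    for m in g:
        for nb in graph.epe_neighbors(m):
            if nb > last:
                cand.add(nb)
    return sorted(cand - set(g))


def oracle_maximal_sets(graph, min_freq=1, min_dist=1000):
    grown: set[frozenset[int]] = set()

    def grow(g):
        grown.add(frozenset(g))
        for v in _candidates(graph, g):
            if _accepts(graph, g, v, min_freq, min_dist):
                grow(g + [v])

    for n in graph.nodes:
        if graph.kind_freq[n.kind] >= min_freq:
            grow([n.node_id])

    return {s for s in grown if not any(s < t for t in grown)}
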