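"""Brute-force reference implementations for small graphs.

These enumerate exhaustively (all matchings, all shortest paths) and are
deliberately independent of the library's algorithms; they are only
feasible for graphs with a handful of nodes.
"""

from __future__ import annotations

from itertools import combinations


def enumerate_matchings(edges):
    """All matchings (as frozensets of edges) of a bipartite edge list,
    where edge (u, v) occupies plus node u and minus node v."""
    edges = list(edges)
    out = []

    def rec(i, used_plus, used_minus, current):
        if i == len(edges):
            out.append(frozenset(current))
            return
        rec(i + 1, used_plus, used_minus, current)
        u, v = edges[i]
        if u not in used_plus and v not in used_minus:
            rec(i + 1, used_plus | {u}, used_minus | {v}, current + [edges[i]])

    rec(0, set(), set(), [])
    return out


def maximum_matchings(edges):
    """All maximum matchings of the bipartite edge list."""
    all_m = enumerate_matchings(edges)
    best = max(len(m) for m in all_m)
    return [m for m in all_m if len(m) == best]


def bipartite_edges(network, include_self_loops=False):
    return [
        (u, v) for u, v in network.links if include_self_loops or u != v
    ]


def all_mdms(network):
    """All distinct minimum driver sets, from exhaustive matching
    enumeration; a perfect matching yields the first node in sorted
    order (mirrors the library's documented rule)."""
    nodes = sorted(network.nodes)
    sets = set()
    for m in maximum_matchings(bipartite_edges(network)):
        matched_minus = {v for _, v in m}
        drivers = frozenset(n for n in nodes if n not in matched_minus)
        if not drivers:
            drivers = frozenset({nodes[0]})
        sets.add(drivers)
    return sets


def node_classes(network):
    """critical / intermittent / redundant from all maximum matchings:
    a node's minus copy is unmatched in all / some / none of them."""
    nodes = sorted(network.nodes)
    mms = maximum_matchings(bipartite_edges(network))
    unmatched_in = {n: 0 for n in nodes}
    for m in mms:
        matched_minus = {v for _, v in m}
        for n in nodes:
            if n not in matched_minus:
                unmatched_in[n] += 1
    out = {}
    for n in nodes:
        if unmatched_in[n] == len(mms):
            out[n] = "critical"
        elif unmatched_in[n] == 0:
            out[n] = "redundant"
        else:
            out[n] = "intermittent"
    return out


def link_classes(network):
    """critical / ordinary / redundant links from all maximum matchings."""
    edges = bipartite_edges(network)
    mms = maximum_matchings(edges)
    out = {}
    for e in network.links:
        if e[0] == e[1]:
            out[e] = "ordinary"  # self-loop: its own alternating cycle
            continue
        hits = sum(1 for m in mms if e in m)
        out[e] = (
            "critical" if hits == len(mms) else "redundant" if hits == 0 else "ordinary"
        )
    return out


def driver_frequencies(network):
    """Exact per-node frequency over all distinct minimum driver sets."""
    sets = all_mdms(network)
    nodes = sorted(network.nodes)
    return {n: sum(1 for s in sets if n in s) / len(sets) for n in nodes}


def betweenness(network):
    """Unnormalized directed betweenness by explicit shortest-path
    counting (BFS distance + path-count DP per source)."""
    g = network.graph
    nodes = list(g.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        c = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.successors(u):
                    if v not in d:
                        d[v] = d[u] + 1
                        c[v] = 0
                        nxt.append(v)
                    if d[v] == d[u] + 1:
                        c[v] += c[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = c
    bet = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                if (
                    v in dist[s]
                    and t in dist[v]
                    and dist[s][v] + dist[v][t] == dist[s][t]
                ):
                    bet[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bet
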