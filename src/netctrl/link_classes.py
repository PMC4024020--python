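"""Link robustness classes: critical / ordinary / redundant.

With respect to controllability, a link is *critical* if it appears in
every maximum matching (its removal raises the number of drivers needed),
*redundant* if it appears in none (removal never changes the driver
requirement), and *ordinary* otherwise.  Following Régin's filtering
argument, the classes are decided from a single arbitrary maximum
matching: orient matched bipartite edges plus -> minus and free edges
minus -> plus (and the reverse orientation), then a link is ordinary iff
it lies on an alternating path starting at a free node in either
orientation or inside a strongly connected component (an alternating
cycle); remaining matched links are critical and remaining free links
redundant.  The result is independent of which maximum matching is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .controllability import maximum_matching, to_bipartite
from .reaction_io import MetaboliteNetwork

__all__ = ["LinkClassTable", "classify_links", "link_class_enrichment"]

LINK_CLASSES = ("critical", "ordinary", "redundant")


@dataclass
class LinkClassTable:
    """Mapping link -> {critical, ordinary, redundant} plus counts."""

    link_class: dict[tuple[str, str], str]

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in LINK_CLASSES}
        for c in self.link_class.values():
            out[c] += 1
        return out

    def links_of_class(self, cls: str) -> list[tuple[str, str]]:
        return [e for e, c in self.link_class.items() if c == cls]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [u for u, _ in self.link_class],
                "target": [v for _, v in self.link_class],
                "class": list(self.link_class.values()),
            }
        ).set_index(["source", "target"])


def _oriented_digraph(edges, matched_of_plus, reverse: bool) -> nx.DiGraph:
    """Bipartite orientation: matched plus->minus, free minus->plus
    (or the exact opposite when ``reverse``)."""
    g = nx.DiGraph()
    for u, v in edges:
        pu, mv = ("+", u), ("-", v)
        g.add_node(pu)
        g.add_node(mv)
        matched = matched_of_plus.get(u) == v
        if matched != reverse:
            g.add_edge(pu, mv)
        else:
            g.add_edge(mv, pu)
    return g


def _edges_reachable_from_free(g: nx.DiGraph, free_nodes) -> set[tuple[str, str]]:
    """Network links whose oriented bipartite edge has its tail reachable
    from a free node (every directed walk from a free node alternates)."""
    reach: set = set()
    for f in free_nodes:
        if f in g and f not in reach:
            reach.update(nx.descendants(g, f))
            reach.add(f)
    marked = set()
    for a, b in g.edges:
        if a in reach:
            u = a[1] if a[0] == "+" else b[1]
            v = b[1] if b[0] == "-" else a[1]
            marked.add((u, v))
    return marked


def classify_links(
    network: MetaboliteNetwork,
    seed: int | None = None,
    include_self_loops: bool = False,
) -> LinkClassTable:
    """Classify every link of the network; see module docstring.

    ``seed`` only randomizes which maximum matching is used; the
    classification is matching-invariant.  Self-loops excluded from the
    matching upstream are their own alternating cycles and come back as
    ordinary.
    """
    bp = to_bipartite(network, include_self_loops=include_self_loops)
    m = maximum_matching(bp, seed=seed)
    matched_of_plus = {u: v for u, v in m.matched_edges}
    matched_minus = m.matched_minus()
    matched_plus = m.matched_plus()

    g1 = _oriented_digraph(bp.edges, matched_of_plus, reverse=False)
    g2 = _oriented_digraph(bp.edges, matched_of_plus, reverse=True)

    free_nodes = [("-", n) for n in bp.minus_nodes if n not in matched_minus] + [
        ("+", n) for n in bp.plus_nodes if n not in matched_plus
    ]
    ordinary = _edges_reachable_from_free(g1, free_nodes)
    ordinary |= _edges_reachable_from_free(g2, free_nodes)

    # alternating cycles = non-trivial SCCs; reversal preserves SCCs, the
    # double computation is kept as a structural cross-check
    scc1 = {frozenset(c) for c in nx.strongly_connected_components(g1) if len(c) > 1}
    scc2 = {frozenset(c) for c in nx.strongly_connected_components(g2) if len(c) > 1}
    assert scc1 == scc2, "SCCs of the two orientations must coincide"
    comp_of = {}
    for comp in scc1:
        for node in comp:
            comp_of[node] = comp
    for u, v in bp.edges:
        cu, cv = comp_of.get(("+", u)), comp_of.get(("-", v))
        if cu is not None and cu is cv:
            ordinary.add((u, v))

    table: dict[tuple[str, str], str] = {}
    for u, v in network.links:
        if u == v and not include_self_loops:
            table[(u, v)] = "ordinary"
        elif (u, v) in ordinary:
            table[(u, v)] = "ordinary"
        elif matched_of_plus.get(u) == v:
            table[(u, v)] = "critical"
        else:
            table[(u, v)] = "redundant"
    return LinkClassTable(link_class=table)


def link_class_enrichment(
    table: LinkClassTable, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tabulate link classes against reaction annotations.

    ``annotations`` is the frame from
    :func:`netctrl.reaction_io.link_annotation_table`.  For each link
    class and for the whole link set ("ensemble"), reports the number of
    links, multi-label counts and fractions per reaction class (a link
    induced by reactions of several classes counts once per class),
    strict unique-class counts, and the fractions of transport and
    environment-to-cell links.  Fractions of an empty link set are NaN.
    """
    missing = [e for e in table.link_class if e not in annotations.index]
    if missing:
        raise ValueError(f"{len(missing)} classified links lack annotations, e.g. {missing[0]}")
    reaction_classes = ("core_high", "core_moderate", "non_core")
    rows = {}
    groups = {cls: table.links_of_class(cls) for cls in LINK_CLASSES}
    groups["ensemble"] = list(table.link_class)
    for name, links in groups.items():
        n = len(links)
        row: dict[str, object] = {"n_links": n}
        sub = annotations.loc[links] if n else annotations.iloc[0:0]
        for rc in reaction_classes:
            multi = int(sub["reaction_classes"].map(lambda cs: rc in cs).sum()) if n else 0
            strict = (
                int(sub["reaction_classes"].map(lambda cs: cs == (rc,)).sum()) if n else 0
            )
            row[f"count_{rc}"] = multi
            row[f"count_strict_{rc}"] = strict
            row[f"frac_{rc}"] = multi / n if n else float("nan")
        row["count_transport"] = int(sub["is_transport"].sum()) if n else 0
        row["frac_transport"] = row["count_transport"] / n if n else float("nan")
        row["count_env_to_cell"] = int(sub["crosses_into_cell"].sum()) if n else 0
        row["frac_env_to_cell"] = row["count_env_to_cell"] / n if n else float("nan")
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
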