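"""Centrality measures, tertile binning and node-set fraction profiles.

Betweenness counts, for ordered pairs (s, t) with s != v != t, the share
of directed shortest s-t paths passing through v (unnormalized, endpoints
excluded).  Out-closeness and in-closeness are reciprocal-distance
(harmonic) sums over directed shortest paths, sum_i 1/d(v,i) and
sum_i 1/d(i,v); plain closeness is the same sum over the undirected
projection.  Unreachable pairs contribute 0, so all values are finite on
disconnected networks.  A config switch offers the classical
1/(sum of distances) closeness for comparison.

For profiling, the node set is split into low/medium/high tertiles per
centrality (deterministic tie rule: sort by score then node id, nominal
cuts at N/3 and 2N/3, a tie group straddling a cut stays in the lower
bin), and the fractions of an interesting node set falling in each
tertile are reported along with the raw counts for chi-square testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .reaction_io import MetaboliteNetwork

__all__ = [
    "TertileFamily",
    "compute_centralities",
    "tertile_split",
    "fraction_profile",
    "CENTRALITY_COLUMNS",
]

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = ("D", "InD", "OutD", "B", "C_out", "C_in", "C")


def _classical_closeness(g: nx.DiGraph | nx.Graph, incoming: bool) -> dict:
    # 1 / sum(d) over reachable pairs, 0 for isolated nodes
    out = {}
    h = g.reverse(copy=False) if (incoming and g.is_directed()) else g
    for v in g.nodes:
        dists = nx.single_source_shortest_path_length(h, v)
        total = sum(d for d in dists.values() if d > 0)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def _harmonic(g: nx.DiGraph | nx.Graph, incoming: bool) -> dict:
    # harmonic_centrality(G)[v] = sum_u 1/d(u, v): incoming distances
    h = g if incoming or not g.is_directed() else g.reverse(copy=False)
    return nx.harmonic_centrality(h)


def compute_centralities(
    network: MetaboliteNetwork, closeness_variant: str = "harmonic"
) -> pd.DataFrame:
    """Per-node degree and centrality table.

    Columns: D (= InD + OutD; a self-loop adds 1 to each), InD, OutD,
    B (betweenness), C_out, C_in (directed closeness), C (closeness on
    the undirected projection).  ``closeness_variant`` is ``"harmonic"``
    (reciprocal-distance sums, the default) or ``"classical"``.
    """
    if closeness_variant not in ("harmonic", "classical"):
        raise ValueError(f"unknown closeness variant {closeness_variant!r}")
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    und = network.undirected(drop_self_loops=True)
    close = _harmonic if closeness_variant == "harmonic" else _classical_closeness
    bet = nx.betweenness_centrality(g, normalized=False)
    c_in = close(g, incoming=True)
    c_out = close(g, incoming=False)
    c_und = close(und, incoming=True)
    rows = []
    for n in network.nodes:
        ind, outd = g.in_degree(n), g.out_degree(n)
        rows.append(
            {
                "node": n,
                "D": ind + outd,
                "InD": ind,
                "OutD": outd,
                "B": bet[n],
                "C_out": c_out[n],
                "C_in": c_in[n],
                "C": c_und[n],
            }
        )
    return pd.DataFrame(rows).set_index("node")


@dataclass(frozen=True)
class TertileFamily:
    """Low/medium/high node sets for one centrality score."""

    low: frozenset[str]
    medium: frozenset[str]
    high: frozenset[str]

    def sets(self) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
        return (self.low, self.medium, self.high)

    @property
    def n(self) -> int:
        return len(self.low) + len(self.medium) + len(self.high)


def tertile_split(scores: Mapping[str, float]) -> TertileFamily:
    """Partition nodes into three score bins of similar sizes.

    Nodes are sorted by (score, id); nominal cut points fall at floor(N/3)
    and floor(2N/3) and a tie group straddling a cut is kept whole in the
    lower bin.  Requires at least 3 nodes.  When every score is equal the
    low bin absorbs everything (logged).
    """
    n = len(scores)
    if n < 3:
        raise ValueError("tertile split needs at least 3 nodes")
    ranked = sorted(scores, key=lambda k: (scores[k], k))

    def push_past_ties(cut: int) -> int:
        while 0 < cut < n and scores[ranked[cut]] == scores[ranked[cut - 1]]:
            cut += 1
        return cut

    c1 = push_past_ties(n // 3)
    c2 = push_past_ties(max(2 * n // 3, c1))
    if c1 == n:
        logger.warning("all %d scores equal: tertile split is degenerate", n)
    return TertileFamily(
        low=frozenset(ranked[:c1]),
        medium=frozenset(ranked[c1:c2]),
        high=frozenset(ranked[c2:]),
    )


def fraction_profile(
    node_set: Iterable[str], families: Mapping[str, TertileFamily]
) -> pd.DataFrame:
    """Intersection fractions of ``node_set`` with each tertile family.

    Returns one row per family with counts and fractions
    |A ∩ low|/|A|, |A ∩ medium|/|A|, |A ∩ high|/|A|; the fractions of a
    non-empty node set sum to 1 when the set lies inside the partitioned
    universe.
    """
    a = set(node_set)
    if not a:
        raise ValueError("node set is empty")
    rows = {}
    for name, fam in families.items():
        cl, cm, ch = (len(a & fam.low), len(a & fam.medium), len(a & fam.high))
        rows[name] = {
            "count_low": cl,
            "count_medium": cm,
            "count_high": ch,
            "frac_low": cl / len(a),
            "frac_medium": cm / len(a),
            "frac_high": ch / len(a),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
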