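"""Structural controllability: maximum matchings and driver metabolites.

A directed network is fully controllable by external inputs attached to
its unmatched nodes, where "matched" refers to a maximum matching of the
bipartite representation: each node X is split into X+ (as a source) and
X- (as a target), and every directed link X -> Y becomes the bipartite
edge (X+, Y-).  A maximum matching is a largest link set sharing no
start or end nodes; the nodes whose minus copy is unmatched form a
minimum driver set of size max(N - |M*|, 1).

Different maximum matchings yield different minimum driver-metabolite
sets (MDMSs).  Enumerating all of them is #P-hard, so driver frequencies
are estimated by repeatedly shuffling the edge list with a seeded RNG,
running Hopcroft-Karp, and deduplicating the resulting driver sets.
Per-node frequencies f_d classify metabolites as critical (f_d = 1),
high-frequency (0.6 <= f_d < 1) or low-frequency (0 <= f_d < 0.6).

The exact critical/intermittent/redundant node classification (driver in
all / some / none of the minimum driver sets) is computed without
enumeration from one maximum matching plus alternating-path
reachability, and the control mode (centralized vs distributed) from the
redundant-node fractions of the network and its transpose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .reaction_io import MetaboliteNetwork

__all__ = [
    "BipartiteGraph",
    "Matching",
    "MDMS",
    "MDMSSample",
    "DriverFrequencyTable",
    "ControlModeResult",
    "to_bipartite",
    "maximum_matching",
    "mdms_from_matching",
    "sample_mdms",
    "driver_frequency",
    "exact_node_control_class",
    "control_mode",
]

logger = logging.getLogger(__name__)

# classification thresholds for sampled driver frequencies, as printed
CRITICAL_FD = Fraction(1)
HIGH_FD_LOWER = Fraction(3, 5)


@dataclass(frozen=True)
class BipartiteGraph:
    """Bipartite representation of a directed network.

    ``edges`` holds pairs (u, v) meaning the bipartite edge (u+, v-),
    i.e. the directed link u -> v.
    """

    plus_nodes: tuple[str, ...]
    minus_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.plus_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Matching:
    """A matching of the bipartite graph: edges sharing no endpoints."""

    matched_edges: frozenset[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.matched_edges)

    def matched_minus(self) -> frozenset[str]:
        return frozenset(v for _, v in self.matched_edges)

    def matched_plus(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.matched_edges)


@dataclass(frozen=True)
class MDMS:
    """A minimum driver-metabolite set."""

    driver_nodes: frozenset[str]

    def __len__(self) -> int:
        return len(self.driver_nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.driver_nodes

    def __iter__(self):
        return iter(self.driver_nodes)


def to_bipartite(
    network: MetaboliteNetwork, include_self_loops: bool = False
) -> BipartiteGraph:
    """Split every node X into X+ / X- and map link X->Y to edge (X+, Y-).

    Self-loops are excluded by default: a self-loop trivially matches its
    own node, which would hide it from the driver analysis.
    """
    nodes = tuple(network.nodes)
    if not nodes:
        raise ValueError("network is empty")
    edges = tuple(
        (u, v)
        for u, v in network.links
        if include_self_loops or u != v
    )
    return BipartiteGraph(plus_nodes=nodes, minus_nodes=nodes, edges=edges)


def _plus(n: str) -> tuple[str, str]:
    return ("+", n)


def _minus(n: str) -> tuple[str, str]:
    return ("-", n)


def maximum_matching(
    bipartite: BipartiteGraph,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Matching:
    """Hopcroft-Karp maximum matching with a randomized edge order.

    The matching size is invariant to edge order; the particular matched
    set is not, which is the sampling handle used by :func:`sample_mdms`:
    node and edge insertion order are shuffled with the seeded RNG before
    the search, so different seeds explore different maximum matchings.
    With ``seed=None`` and ``rng=None`` the canonical input order is used
    and the result is deterministic.
    """
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    plus = list(bipartite.plus_nodes)
    minus = list(bipartite.minus_nodes)
    edges = list(bipartite.edges)
    if rng is not None:
        rng.shuffle(plus)
        rng.shuffle(minus)
        rng.shuffle(edges)
    g = nx.Graph()
    g.add_nodes_from(_plus(n) for n in plus)
    g.add_nodes_from(_minus(n) for n in minus)
    g.add_edges_from((_plus(u), _minus(v)) for u, v in edges)
    raw = nx.bipartite.hopcroft_karp_matching(g, top_nodes=[_plus(n) for n in plus])
    matched = frozenset(
        (key[1], val[1]) for key, val in raw.items() if key[0] == "+"
    )
    return Matching(matched_edges=matched)


def _check_maximum(network: MetaboliteNetwork, matching: Matching,
                   include_self_loops: bool = False) -> BipartiteGraph:
    bp = to_bipartite(network, include_self_loops=include_self_loops)
    best = maximum_matching(bp)
    if matching.size != best.size:
        raise ValueError(
            f"matching of size {matching.size} is not maximum (maximum is {best.size})"
        )
    return bp


def mdms_from_matching(
    network: MetaboliteNetwork,
    matching: Matching,
    include_self_loops: bool = False,
) -> MDMS:
    """Drivers are the nodes whose minus copy the matching leaves free.

    For a perfect matching the empty driver set is replaced by the single
    node first in canonical (sorted id) order, so that |MDMS| is always
    max(N - |M*|, 1).
    """
    _check_maximum(network, matching, include_self_loops)
    matched_minus = matching.matched_minus()
    drivers = frozenset(n for n in network.nodes if n not in matched_minus)
    if not drivers:
        drivers = frozenset({min(network.nodes)})
    return MDMS(driver_nodes=drivers)


@dataclass
class MDMSSample:
    """Distinct MDMSs found by randomized matching sampling."""

    mdms_sets: list[MDMS]
    n_matchings_sampled: int
    n_distinct_matchings: int
    matching_size: int
    seed: int | None

    def __iter__(self):
        return iter(self.mdms_sets)

    def __len__(self) -> int:
        return len(self.mdms_sets)

    def __getitem__(self, i):
        return self.mdms_sets[i]


def sample_mdms(
    network: MetaboliteNetwork,
    n_samples: int,
    seed: int | None = None,
    include_self_loops: bool = False,
) -> MDMSSample:
    """Sample ``n_samples`` randomized maximum matchings and return the
    distinct driver sets they induce.

    Deduplication happens at the driver-set level; the number of distinct
    matchings seen is also recorded.  If the network admits fewer
    distinct MDMSs than requested, all found are returned (with a logged
    warning only when sampling saturated early and found few sets).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    bp = to_bipartite(network, include_self_loops=include_self_loops)
    rng = np.random.default_rng(seed)
    node_order = sorted(network.nodes)
    seen_matchings: set[frozenset[tuple[str, str]]] = set()
    seen_drivers: set[frozenset[str]] = set()
    out: list[MDMS] = []
    size = None
    for _ in range(n_samples):
        m = maximum_matching(bp, rng=rng)
        if size is None:
            size = m.size
        elif m.size != size:  # pragma: no cover - HK contract
            raise AssertionError("sampled matchings differ in size")
        seen_matchings.add(m.matched_edges)
        matched_minus = m.matched_minus()
        drivers = frozenset(n for n in node_order if n not in matched_minus)
        if not drivers:
            drivers = frozenset({node_order[0]})
        if drivers not in seen_drivers:
            seen_drivers.add(drivers)
            out.append(MDMS(driver_nodes=drivers))
    if len(out) < n_samples:
        logger.warning(
            "requested %d samples but found %d distinct MDMSs "
            "(%d distinct matchings)",
            n_samples,
            len(out),
            len(seen_matchings),
        )
    return MDMSSample(
        mdms_sets=out,
        n_matchings_sampled=n_samples,
        n_distinct_matchings=len(seen_matchings),
        matching_size=size if size is not None else 0,
        seed=seed,
    )


@dataclass
class DriverFrequencyTable:
    """Per-node driver frequency f_d and its 3-way classification.

    Frequencies are kept as exact integer counts over ``sample_count``
    distinct MDMSs; the printed thresholds (f_d = 1 critical,
    0.6 <= f_d < 1 high-frequency, below low-frequency) are applied to
    the exact ratio, never to a rounded float.
    """

    counts: dict[str, int]
    sample_count: int

    @property
    def f_d(self) -> dict[str, float]:
        return {n: c / self.sample_count for n, c in self.counts.items()}

    def frequency(self, node: str) -> Fraction:
        return Fraction(self.counts[node], self.sample_count)

    @property
    def classes(self) -> dict[str, str]:
        out = {}
        for n in self.counts:
            f = self.frequency(n)
            if f == CRITICAL_FD:
                out[n] = "critical"
            elif f >= HIGH_FD_LOWER:
                out[n] = "high_frequency"
            else:
                out[n] = "low_frequency"
        return out

    def as_frame(self) -> pd.DataFrame:
        cls = self.classes
        return pd.DataFrame(
            {
                "node": list(self.counts),
                "f_d": [c / self.sample_count for c in self.counts.values()],
                "class": [cls[n] for n in self.counts],
            }
        ).set_index("node")


def driver_frequency(
    samples: Sequence[MDMS] | MDMSSample,
    nodes: Iterable[str] | None = None,
) -> DriverFrequencyTable:
    """Empirical per-node frequency across distinct MDMS samples.

    ``nodes`` fixes the node universe (nodes absent from every sample get
    f_d = 0); by default the union of the samples is used.
    """
    sets = list(samples)
    if not sets:
        raise ValueError("need at least one MDMS sample")
    universe = list(nodes) if nodes is not None else sorted(
        {n for s in sets for n in s.driver_nodes}
    )
    counts = {n: 0 for n in universe}
    for s in sets:
        for n in s.driver_nodes:
            counts[n] += 1
    return DriverFrequencyTable(counts=counts, sample_count=len(sets))


def exact_node_control_class(
    network: MetaboliteNetwork, include_self_loops: bool = False
) -> dict[str, str]:
    """Classify each node as critical / intermittent / redundant.

    A node is a possible driver (appears in some minimum driver set) iff
    its minus copy is left unmatched by some maximum matching; it is
    critical iff unmatched by every one.  Both conditions reduce to one
    maximum matching plus alternating-path reachability:

    - a minus node with no incident bipartite edge (in-degree 0, self
      loops excluded by default) can never be matched -> critical;
    - a matched minus node can be freed iff it is reachable from some
      free minus node along the orientation where matched edges run
      plus -> minus and free edges minus -> plus; then it is a possible
      driver (intermittent), otherwise it is matched in every maximum
      matching -> redundant;
    - an unmatched, non-isolated minus node is intermittent (any of its
      edges can be swapped into some maximum matching).
    """
    bp = to_bipartite(network, include_self_loops=include_self_loops)
    m = maximum_matching(bp)
    matched_of_plus = {u: v for u, v in m.matched_edges}
    matched_minus = m.matched_minus()
    in_edges: dict[str, list[str]] = {n: [] for n in bp.minus_nodes}
    for u, v in bp.edges:
        in_edges[v].append(u)
    # BFS over minus nodes in the matched orientation:
    # minus -> (free edge) -> plus -> (its matched edge) -> minus
    free_minus = [n for n in bp.minus_nodes if n not in matched_minus]
    reachable: set[str] = set(free_minus)
    stack = list(free_minus)
    visited_plus: set[str] = set()
    while stack:
        v = stack.pop()
        for u in in_edges[v]:
            if u in visited_plus:
                continue
            if matched_of_plus.get(u) == v:
                continue  # (u+, v-) is the matched edge, not free
            visited_plus.add(u)
            nxt = matched_of_plus.get(u)
            if nxt is not None and nxt not in reachable:
                reachable.add(nxt)
                stack.append(nxt)
    classes = {}
    for n in network.nodes:
        if not in_edges[n]:
            classes[n] = "critical"
        elif n not in matched_minus or n in reachable:
            classes[n] = "intermittent"
        else:
            classes[n] = "redundant"
    return classes


@dataclass
class ControlModeResult:
    """Redundant-node fractions of a network and its transpose.

    ``mode`` is centralized when delta_n_r = n_r - n_r_T > 0, distributed
    when < 0, indeterminate when exactly 0.
    """

    node_class: dict[str, str]
    n_r: Fraction
    n_r_T: Fraction
    mode: str

    @property
    def delta_n_r(self) -> Fraction:
        return self.n_r - self.n_r_T


def control_mode(
    network: MetaboliteNetwork, include_self_loops: bool = False
) -> ControlModeResult:
    """Identify the control mode from exact node classes on the network
    and on its transpose (all links reversed)."""
    classes = exact_node_control_class(network, include_self_loops)
    classes_t = exact_node_control_class(network.transpose(), include_self_loops)
    n = network.n_nodes
    n_r = Fraction(sum(1 for c in classes.values() if c == "redundant"), n)
    n_r_t = Fraction(sum(1 for c in classes_t.values() if c == "redundant"), n)
    delta = n_r - n_r_t
    mode = "centralized" if delta > 0 else "distributed" if delta < 0 else "indeterminate"
    return ControlModeResult(node_class=classes, n_r=n_r, n_r_T=n_r_t, mode=mode)
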