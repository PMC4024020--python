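"""Reaction-list parsing and metabolite-network construction.

A metabolic model is given as a plain-text list of reactions over
compartmentalized metabolites written ``name[compartment]`` — the same
metabolite in two compartments is two distinct network nodes.  The model
is turned into a directed graph with one node per compartment-specific
metabolite and a link ``A[x] -> B[y]`` whenever some reaction consumes
``A[x]`` and produces ``B[y]``.  Each link remembers the reaction(s) that
induced it, so downstream analyses can relate link-level results back to
reaction annotations (core class, transport status).

Reaction-list dialect, one record per line::

    RID: m1[c1] + m2[c2] -> p1[c3] ; class=core_high ; rev=0

``<->`` (or ``rev=1``) marks a reversible reaction.  A tab-separated form
with columns ``id, substrates, products, class, rev`` is also accepted
(substrates/products joined by ``+`` or ``,``).  Lines starting with ``#``
and blank lines are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "CompartmentalizedMetabolite",
    "Reaction",
    "MetaboliteNetwork",
    "ReactionParseError",
    "REACTION_CLASSES",
    "parse_reactions",
    "serialize_reactions",
    "build_network",
    "link_annotation_table",
]

REACTION_CLASSES = ("core_high", "core_moderate", "non_core", "unlabeled")

_MET_RE = re.compile(r"^(?P<name>[^\[\]]+)\[(?P<comp>[^\[\]\s]+)\]$")


class ReactionParseError(ValueError):
    """Malformed reaction record; message names the offending line."""


@dataclass(frozen=True, order=True)
class CompartmentalizedMetabolite:
    """A metabolite qualified by the cell compartment it appears in."""

    base_name: str
    compartment: str

    def __post_init__(self) -> None:
        if not self.base_name or not self.compartment:
            raise ValueError("metabolite name and compartment must be non-empty")

    @property
    def id(self) -> str:
        return f"{self.base_name}[{self.compartment}]"

    @classmethod
    def parse(cls, token: str) -> "CompartmentalizedMetabolite":
        m = _MET_RE.match(token.strip())
        if m is None:
            raise ReactionParseError(
                f"malformed metabolite token {token!r}: expected name[compartment]"
            )
        return cls(m.group("name").strip(), m.group("comp").strip())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


@dataclass(frozen=True)
class Reaction:
    """One metabolic reaction: substrates -> products, with annotations.

    ``is_transport`` is derived: true iff the substrates and products span
    at least two distinct compartments.
    """

    id: str
    substrates: frozenset[CompartmentalizedMetabolite]
    products: frozenset[CompartmentalizedMetabolite]
    reversible: bool = False
    reaction_class: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.id}: empty substrate or product side")
        if self.reaction_class not in REACTION_CLASSES:
            raise ValueError(
                f"reaction {self.id}: unknown class {self.reaction_class!r}"
            )

    @property
    def compartments(self) -> frozenset[str]:
        return frozenset(
            m.compartment for m in self.substrates | self.products
        )

    @property
    def is_transport(self) -> bool:
        return len(self.compartments) >= 2

    def crosses_into_cell(self, extracellular: str = "e") -> bool:
        """True iff this reaction moves material from the extracellular
        compartment into a non-extracellular one."""
        return any(s.compartment == extracellular for s in self.substrates) and any(
            p.compartment != extracellular for p in self.products
        )


def _parse_side(side: str, line_no: int) -> frozenset[CompartmentalizedMetabolite]:
    tokens = [t.strip() for t in side.split("+")]
    if not tokens or any(not t for t in tokens):
        raise ReactionParseError(f"line {line_no}: empty metabolite term in {side!r}")
    try:
        return frozenset(CompartmentalizedMetabolite.parse(t) for t in tokens)
    except ReactionParseError as exc:
        raise ReactionParseError(f"line {line_no}: {exc}") from exc


def _parse_record_line(line: str, line_no: int) -> Reaction:
    head, _, tail = line.partition(":")
    rid = head.strip()
    if not rid or not tail.strip():
        raise ReactionParseError(f"line {line_no}: expected 'RID: substrates -> products'")
    parts = [p.strip() for p in tail.split(";")]
    eqn = parts[0]
    reversible = False
    if "<->" in eqn:
        lhs, _, rhs = eqn.partition("<->")
        reversible = True
    elif "->" in eqn:
        lhs, _, rhs = eqn.partition("->")
    else:
        raise ReactionParseError(f"line {line_no}: no '->' or '<->' arrow found")
    rclass = "unlabeled"
    for opt in parts[1:]:
        if not opt:
            continue
        key, _, val = opt.partition("=")
        key, val = key.strip(), val.strip()
        if key == "class":
            rclass = val
        elif key == "rev":
            reversible = val in ("1", "true", "True")
        else:
            raise ReactionParseError(f"line {line_no}: unknown annotation {key!r}")
    if not lhs.strip() or not rhs.strip():
        raise ReactionParseError(f"line {line_no}: empty side of reaction {rid!r}")
    try:
        return Reaction(
            id=rid,
            substrates=_parse_side(lhs, line_no),
            products=_parse_side(rhs, line_no),
            reversible=reversible,
            reaction_class=rclass,
        )
    except ValueError as exc:
        raise ReactionParseError(f"line {line_no}: {exc}") from exc


def _parse_tabular_line(line: str, line_no: int) -> Reaction:
    cols = line.split("\t")
    if len(cols) < 3:
        raise ReactionParseError(
            f"line {line_no}: tabular record needs >=3 columns (id, substrates, products)"
        )
    rid = cols[0].strip()
    subs = cols[1].replace(",", "+")
    prods = cols[2].replace(",", "+")
    rclass = cols[3].strip() if len(cols) > 3 and cols[3].strip() else "unlabeled"
    rev = cols[4].strip() in ("1", "true", "True") if len(cols) > 4 else False
    if not rid:
        raise ReactionParseError(f"line {line_no}: empty reaction id")
    try:
        return Reaction(
            id=rid,
            substrates=_parse_side(subs, line_no),
            products=_parse_side(prods, line_no),
            reversible=rev,
            reaction_class=rclass,
        )
    except ValueError as exc:
        raise ReactionParseError(f"line {line_no}: {exc}") from exc


def parse_reactions(text: str | Path) -> list[Reaction]:
    """Parse a reaction-list document into :class:`Reaction` records.

    ``text`` may be the document itself or a path to it.  Records may mix
    the colon dialect and the tab-separated form; duplicate reaction ids
    raise :class:`ReactionParseError`.
    """
    if isinstance(text, Path):
        text = text.read_text()
    reactions: list[Reaction] = []
    seen: set[str] = set()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line and ":" not in line.partition("\t")[0]:
            rxn = _parse_tabular_line(line, line_no)
        else:
            rxn = _parse_record_line(line, line_no)
        if rxn.id in seen:
            raise ReactionParseError(f"line {line_no}: duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        reactions.append(rxn)
    return reactions


def serialize_reactions(reactions: Iterable[Reaction]) -> str:
    """Render reactions in the colon dialect (stable ordering within sides)."""
    lines = []
    for r in reactions:
        arrow = "<->" if r.reversible else "->"
        lhs = " + ".join(m.id for m in sorted(r.substrates))
        rhs = " + ".join(m.id for m in sorted(r.products))
        lines.append(f"{r.id}: {lhs} {arrow} {rhs} ; class={r.reaction_class} ; rev={int(r.reversible)}")
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class MetaboliteNetwork:
    """Directed network of compartment-specific metabolites.

    Thin wrapper around a :class:`networkx.DiGraph`; ``link_reactions``
    maps each directed link to the set of reaction ids that induced it
    (empty for generic edge-list imports).  Parallel inductions collapse
    to a single link.  Self-loops are retained and queryable.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    link_reactions: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "MetaboliteNetwork":
        net = cls()
        for u, v in edges:
            net.add_link(str(u), str(v))
        return net

    @classmethod
    def from_edgelist(cls, source: str | Path) -> "MetaboliteNetwork":
        """Read a two-column whitespace-separated edge list."""
        text = source.read_text() if isinstance(source, Path) else source
        edges = []
        for line_no, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"edge list line {line_no}: expected two columns")
            edges.append((parts[0], parts[1]))
        return cls.from_edges(edges)

    def to_edgelist(self) -> str:
        return "\n".join(f"{u} {v}" for u, v in sorted(self.links)) + (
            "\n" if self.graph.number_of_edges() else ""
        )

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_link(self, u: str, v: str, reaction_id: str | None = None) -> None:
        self.graph.add_edge(u, v)
        bucket = self.link_reactions.setdefault((u, v), set())
        if reaction_id is not None:
            bucket.add(reaction_id)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def links(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def self_loops(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self.graph.edges if u == v]

    def in_degree(self, node: str, count_self_loops: bool = True) -> int:
        d = self.graph.in_degree(node)
        if not count_self_loops and self.graph.has_edge(node, node):
            d -= 1
        return d

    def transpose(self) -> "MetaboliteNetwork":
        rev = MetaboliteNetwork(graph=self.graph.reverse(copy=True))
        rev.link_reactions = {
            (v, u): set(rids) for (u, v), rids in self.link_reactions.items()
        }
        return rev

    def undirected(self, drop_self_loops: bool = True) -> nx.Graph:
        """Undirected projection: reciprocal link pairs collapse to one edge."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v in self.graph.edges:
            if drop_self_loops and u == v:
                continue
            g.add_edge(u, v)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaboliteNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.links) == set(other.links)


def build_network(
    reactions: Sequence[Reaction], expand_reversible: bool = True
) -> MetaboliteNetwork:
    """Build the directed metabolite network from parsed reactions.

    Every substrate gains a link to every product of the same reaction;
    reversible reactions additionally contribute the product->substrate
    links (switchable with ``expand_reversible``).  Duplicate directed
    pairs collapse to one link carrying the union of inducing reaction
    ids.  Self-loops (a metabolite on both sides of one reaction) are
    retained and flagged via :attr:`MetaboliteNetwork.self_loops`.
    """
    net = MetaboliteNetwork()
    for r in reactions:
        for m in r.substrates | r.products:
            net.add_node(m.id)
        for s in r.substrates:
            for p in r.products:
                net.add_link(s.id, p.id, r.id)
        if r.reversible and expand_reversible:
            for p in r.products:
                for s in r.substrates:
                    net.add_link(p.id, s.id, r.id)
    return net


def link_annotation_table(
    network: MetaboliteNetwork,
    reactions: Sequence[Reaction],
    extracellular: str = "e",
) -> pd.DataFrame:
    """Per-link attributes derived from the inducing reactions.

    Returns a DataFrame indexed by (source, target) with columns:

    - ``reaction_classes``: sorted tuple of the distinct classes of the
      inducing reactions (a link may carry several);
    - ``is_transport``: any inducing reaction is a transport reaction;
    - ``crosses_into_cell``: any inducing reaction moves material from
      the extracellular compartment into the cell;
    - ``n_reactions``: number of inducing reactions.

    Raises ``ValueError`` for a link with no inducing reaction (internal
    consistency: the network must have been built from these reactions).
    """
    by_id = {r.id: r for r in reactions}
    rows = []
    for link in network.links:
        rids = network.link_reactions.get(link, set())
        if not rids:
            raise ValueError(f"link {link} has no inducing reaction")
        rxns = [by_id[rid] for rid in sorted(rids)]
        rows.append(
            {
                "source": link[0],
                "target": link[1],
                "reaction_classes": tuple(sorted({r.reaction_class for r in rxns})),
                "is_transport": any(r.is_transport for r in rxns),
                "crosses_into_cell": any(
                    r.crosses_into_cell(extracellular) for r in rxns
                ),
                "n_reactions": len(rxns),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "reaction_classes",
            "is_transport",
            "crosses_into_cell",
            "n_reactions",
        ],
    )
    return frame.set_index(["source", "target"])
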