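"""Synthetic reaction sets and benchmark networks.

Two generators make the whole pipeline testable without a curated liver
model file:

- :func:`generate_reactions` emits a compartmentalized reaction list
  with the structural features the analysis relies on: a designated set
  of extracellular *boundary* metabolites that appear only as substrates
  (hence in-degree 0, structurally forced drivers in the built network),
  transport reactions crossing compartments, a 3-way core-high /
  core-moderate / non-core class mix, and small multi-substrate
  reactions with side sizes drawn from a truncated geometric law.
  Defaults mirror a liver-scale model: 1360 metabolites, 1826 reactions,
  ~2.6% boundary metabolites, ~20% transport reactions and a
  60/14.5/25.5 class mix.

- :func:`generate_planted_network` plants a known modular partition
  (within/between link probabilities) for module-recovery and role
  benchmarks.

Both are pure functions of (spec, seed).  :func:`fixture_gallery`
bundles tiny named networks with hand-checkable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reaction_io import (
    CompartmentalizedMetabolite,
    MetaboliteNetwork,
    Reaction,
    build_network,
    parse_reactions,
)

__all__ = [
    "SyntheticModelSpec",
    "PlantedPartitionSpec",
    "generate_reactions",
    "generate_planted_network",
    "fixture_gallery",
    "FIG1_REACTIONS",
]

# three-reaction toy model: an oxidation, a transport step and an
# intracellular condensation across cytoplasm [c] and mitochondrion [m]
FIG1_REACTIONS = """\
R1: hgentis[c] + o2[c] -> 4mlacac[c] + h[c]
R2: h[c] -> h[m]
R3: h[m] + hco3[m] -> h2co3[m]
"""


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Parameters of a synthetic compartmentalized metabolic model."""

    n_metabolites: int = 1360
    n_reactions: int = 1826
    compartments: tuple[str, ...] = ("c", "m", "e")
    extracellular: str = "e"
    fraction_transport: float = 0.2
    fraction_boundary: float = 0.026
    class_mix: tuple[float, float, float] = (0.60, 0.145, 0.255)
    fraction_reversible: float = 0.1
    max_side_size: int = 4
    side_geometric_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_transport", "fraction_boundary", "fraction_reversible"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.extracellular not in self.compartments:
            raise ValueError("extracellular code must be one of the compartments")
        if self.fraction_transport > 0 and len(self.compartments) < 2:
            raise ValueError("transport reactions require at least two compartments")
        if self.n_metabolites < 4 or self.n_reactions < 1:
            raise ValueError("spec too small to generate a model")


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of a directed planted-partition benchmark network."""

    n_modules: int = 4
    nodes_per_module: int = 25
    p_within: float = 0.3
    p_between: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_within <= 1.0 and 0.0 <= self.p_between <= 1.0):
            raise ValueError("link probabilities must be in [0, 1]")
        if self.n_modules < 1 or self.nodes_per_module < 1:
            raise ValueError("need at least one module with at least one node")


def _truncated_geometric(rng: np.random.Generator, p: float, high: int) -> int:
    # support 1..high
    while True:
        k = int(rng.geometric(p))
        if k <= high:
            return k


def generate_reactions(spec: SyntheticModelSpec) -> list[Reaction]:
    """Generate a reaction list honoring the spec (see module docstring).

    Boundary metabolites live in the extracellular compartment and are
    used only as substrates, each of them at least once, so the built
    network is guaranteed to contain them as in-degree-0 nodes.
    Reactions with a boundary substrate are forced irreversible (a
    reverse link would give the boundary metabolite positive in-degree).
    """
    rng = np.random.default_rng(spec.seed)
    n_boundary = int(round(spec.fraction_boundary * spec.n_metabolites))
    names = [f"M{i:04d}" for i in range(spec.n_metabolites)]
    mets: list[CompartmentalizedMetabolite] = []
    boundary: list[CompartmentalizedMetabolite] = []
    for i, name in enumerate(names):
        if i < n_boundary:
            comp = spec.extracellular
        else:
            comp = spec.compartments[int(rng.integers(len(spec.compartments)))]
        m = CompartmentalizedMetabolite(name, comp)
        mets.append(m)
        if i < n_boundary:
            boundary.append(m)
    boundary_set = set(boundary)
    interior = [m for m in mets if m not in boundary_set]
    by_comp: dict[str, list[CompartmentalizedMetabolite]] = {}
    for m in interior:
        by_comp.setdefault(m.compartment, []).append(m)
    usable_comps = [c for c in spec.compartments if by_comp.get(c)]
    if len(usable_comps) < 1:
        raise ValueError("no interior metabolites to act as products")

    n_transport = int(round(spec.fraction_transport * spec.n_reactions))
    if n_boundary > n_transport:
        raise ValueError(
            f"infeasible spec: {n_boundary} boundary metabolites need at least "
            f"as many transport reactions to enter the network, got {n_transport}"
        )
    class_labels = ("core_high", "core_moderate", "non_core")
    classes = rng.choice(3, size=spec.n_reactions, p=list(spec.class_mix))

    def pick(pool: Sequence[CompartmentalizedMetabolite], k: int):
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[int(i)] for i in idx]

    reactions: list[Reaction] = []
    boundary_cycle = list(boundary)
    rng.shuffle(boundary_cycle)  # type: ignore[arg-type]
    for r in range(spec.n_reactions):
        is_transport = r < n_transport
        n_sub = _truncated_geometric(rng, spec.side_geometric_p, spec.max_side_size)
        n_prod = _truncated_geometric(rng, spec.side_geometric_p, spec.max_side_size)
        if is_transport:
            # substrates in one compartment, products in a different one;
            # early transport reactions carry the boundary intake so every
            # boundary metabolite enters the network as a substrate
            if boundary_cycle:
                anchor = boundary_cycle.pop()
                sub_comp = anchor.compartment
                subs = [anchor] + pick(
                    [m for m in boundary if m is not anchor], n_sub - 1
                )
            else:
                sub_comp = usable_comps[int(rng.integers(len(usable_comps)))]
                subs = pick(by_comp[sub_comp], n_sub)
            prod_choices = [c for c in usable_comps if c != sub_comp]
            if not prod_choices:
                raise ValueError(
                    "transport infeasible: need interior metabolites outside "
                    f"compartment {sub_comp!r}"
                )
            prod_comp = prod_choices[int(rng.integers(len(prod_choices)))]
            prods = pick(by_comp[prod_comp], n_prod)
        else:
            comp = usable_comps[int(rng.integers(len(usable_comps)))]
            pool = by_comp[comp]
            subs = pick(pool, n_sub)
            prods = pick([m for m in pool if m not in subs] or pool, n_prod)
        has_boundary = any(m in boundary_set for m in subs)
        reversible = (not has_boundary) and rng.random() < spec.fraction_reversible
        reactions.append(
            Reaction(
                id=f"R{r:04d}",
                substrates=frozenset(subs),
                products=frozenset(prods),
                reversible=reversible,
                reaction_class=class_labels[int(classes[r])],
            )
        )
    return reactions


def generate_planted_network(
    spec: PlantedPartitionSpec,
) -> tuple[MetaboliteNetwork, dict[str, int]]:
    """Directed planted-partition network plus the planted module labels.

    Every ordered pair (i, j), i != j, carries a link independently with
    probability ``p_within`` when i and j share a planted module and
    ``p_between`` otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_modules * spec.nodes_per_module
    labels = {
        f"n{i:03d}": i // spec.nodes_per_module for i in range(n)
    }
    nodes = list(labels)
    net = MetaboliteNetwork()
    for v in nodes:
        net.add_node(v)
    probs = rng.random((n, n))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i == j:
                continue
            p = spec.p_within if labels[u] == labels[v] else spec.p_between
            if probs[i, j] < p:
                net.add_link(u, v)
    return net, labels


def _two_cliques(size: int = 10) -> MetaboliteNetwork:
    net = MetaboliteNetwork()
    for block, prefix in ((0, "a"), (1, "b")):
        names = [f"{prefix}{i}" for i in range(size)]
        for v in names:
            net.add_node(v)
        for i in range(size):
            for j in range(i + 1, size):
                net.add_link(names[i], names[j])
    return net


def fixture_gallery() -> dict[str, MetaboliteNetwork]:
    """Deterministic small networks with hand-checkable structure.

    - ``path3``: a -> b -> c (unique driver set {a});
    - ``cycle3``: 3-cycle, perfect matching, all links critical;
    - ``star4``: h -> l1, l2, l3 (three driver sets of size 3);
    - ``two_cliques``: two disjoint 10-cliques, optimal 2-module
      partition with M = 0.5;
    - ``fig1``: the 7-node network of the three-reaction toy model;
    - ``fan5``: two sources feeding a shared middle layer draining into
      one sink, a small worked example with several maximum matchings.
    """
    fig1 = build_network(parse_reactions(FIG1_REACTIONS))
    return {
        "path3": MetaboliteNetwork.from_edges([("a", "b"), ("b", "c")]),
        "cycle3": MetaboliteNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")]),
        "star4": MetaboliteNetwork.from_edges([("h", "l1"), ("h", "l2"), ("h", "l3")]),
        "two_cliques": _two_cliques(10),
        "fig1": fig1,
        "fan5": MetaboliteNetwork.from_edges(
            [("x1", "x3"), ("x2", "x3"), ("x2", "x4"), ("x3", "x5"), ("x4", "x5")]
        ),
    }
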