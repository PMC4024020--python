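"""Module detection by simulated annealing and node role cartography.

Modularity of a partition of an undirected simple graph is

    M = sum_s [ l_s / L - (d_s / 2L)^2 ]

with L the number of edges, l_s the edges inside module s and d_s the
total degree of module s.  M = 0 for the single-module partition and for
random assignments; a good decomposition has many within-module edges
beyond the degree-preserving expectation.

The optimizer anneals the cost C = -M: at each temperature T it attempts
n_i = f*S^2 single-node moves and n_c = f*S collective moves (merging
two random modules or splitting one via a short inner refinement), each
accepted with probability 1 if the cost does not increase and
exp(-(C_f - C_i)/T) otherwise; T is then cooled to c*T with c = 0.965.
The directed metabolite network is symmetrized first (reciprocal links
collapse to one undirected edge; self-loops dropped).

Roles follow the within-module degree / participation coefficient
cartography: z_i is the z-score of a node's intra-module degree within
its module, P_i = 1 - sum_s (k_is / k_i)^2, and the seven classes split
at z = 2.5 (hub vs non-hub), P = 0.05 / 0.62 / 0.80 for non-hubs (R1-R4)
and P = 0.30 / 0.75 for hubs (R5-R7), all boundaries inclusive on the
lower class as printed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .reaction_io import MetaboliteNetwork

__all__ = [
    "Partition",
    "SAConfig",
    "RoleTable",
    "modularity",
    "simulated_annealing",
    "assign_roles",
    "role_frequency_stability",
    "driver_role_profile",
    "ROLES",
]

logger = logging.getLogger(__name__)

ROLES = ("R1", "R2", "R3", "R4", "R5", "R6", "R7")
HUB_Z = 2.5
NONHUB_P_SPLITS = (0.05, 0.62, 0.80)
HUB_P_SPLITS = (0.30, 0.75)


@dataclass
class Partition:
    """A module assignment with its modularity."""

    assignment: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for n, s in self.assignment.items():
            out.setdefault(s, []).append(n)
        return out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.assignment), "module": list(self.assignment.values())}
        ).set_index("node")


@dataclass
class SAConfig:
    """Annealing schedule parameters.

    ``f`` scales the per-temperature move counts (n_i = f*S^2 individual,
    n_c = f*S collective); ``c`` is the cooling factor.  ``T0`` defaults
    to a calibration pre-pass choosing the temperature at which at least
    ~90% of initial proposals are accepted.  Cooling stops below
    ``t_min_ratio * T0`` or after ``patience`` consecutive temperatures
    without an accepted move.
    """

    f: float = 1.0
    c: float = 0.965
    T0: float | None = None
    t_min_ratio: float = 1e-4
    patience: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.c < 1):
            raise ValueError("cooling factor c must be in (0, 1)")
        if self.f <= 0:
            raise ValueError("iteration factor f must be > 0")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def _as_undirected(network: MetaboliteNetwork | nx.Graph) -> nx.Graph:
    if isinstance(network, MetaboliteNetwork):
        return network.undirected(drop_self_loops=True)
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((u, v) for u, v in network.edges if u != v)
    return g


def modularity(
    network: MetaboliteNetwork | nx.Graph, partition: Mapping[str, int]
) -> float:
    """Evaluate M on the undirected projection of the network.

    Raises ``ValueError`` when a node is missing from the partition.  A
    network without edges has M = 0 for every partition.
    """
    g = _as_undirected(network)
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition misses {len(missing)} nodes, e.g. {missing[0]!r}")
    L = g.number_of_edges()
    if L == 0:
        return 0.0
    l_s: dict[int, int] = {}
    d_s: dict[int, int] = {}
    for n in g.nodes:
        d_s[partition[n]] = d_s.get(partition[n], 0) + g.degree(n)
    for u, v in g.edges:
        if partition[u] == partition[v]:
            l_s[partition[u]] = l_s.get(partition[u], 0) + 1
    return sum(
        l_s.get(s, 0) / L - (d / (2 * L)) ** 2 for s, d in d_s.items()
    )


class _SAState:
    """Incremental modularity bookkeeping over integer-indexed nodes."""

    def __init__(self, adj: list[list[int]], deg: np.ndarray, L: int, comm: np.ndarray):
        self.adj = adj
        self.deg = deg
        self.L = L
        self.comm = comm
        self.l_s: dict[int, int] = {}
        self.d_s: dict[int, int] = {}
        for i, c in enumerate(comm):
            self.d_s[int(c)] = self.d_s.get(int(c), 0) + int(deg[i])
        for i in range(len(adj)):
            for j in adj[i]:
                if j > i and comm[i] == comm[j]:
                    c = int(comm[i])
                    self.l_s[c] = self.l_s.get(c, 0) + 1
        self.next_label = int(comm.max()) + 1 if len(comm) else 0

    def mod(self) -> float:
        L = self.L
        return sum(
            self.l_s.get(s, 0) / L - (d / (2 * L)) ** 2 for s, d in self.d_s.items()
        )

    def links_to(self, i: int, module: int) -> int:
        comm = self.comm
        return sum(1 for j in self.adj[i] if comm[j] == module and j != i)

    # -- individual node move -----------------------------------------
    def delta_move(self, i: int, b: int) -> float:
        a = int(self.comm[i])
        if a == b:
            return 0.0
        L = self.L
        k = int(self.deg[i])
        kia = self.links_to(i, a)
        kib = self.links_to(i, b)
        da, db = self.d_s.get(a, 0), self.d_s.get(b, 0)
        before = -((da / (2 * L)) ** 2) - (db / (2 * L)) ** 2
        after = -(((da - k) / (2 * L)) ** 2) - (((db + k) / (2 * L)) ** 2)
        return (kib - kia) / L + after - before

    def apply_move(self, i: int, b: int) -> None:
        a = int(self.comm[i])
        k = int(self.deg[i])
        kia = self.links_to(i, a)
        kib = self.links_to(i, b)
        self.l_s[a] = self.l_s.get(a, 0) - kia
        self.l_s[b] = self.l_s.get(b, 0) + kib
        self.d_s[a] = self.d_s.get(a, 0) - k
        self.d_s[b] = self.d_s.get(b, 0) + k
        if self.d_s[a] == 0:
            del self.d_s[a]
            self.l_s.pop(a, None)
        self.comm[i] = b

    # -- merge --------------------------------------------------------
    def delta_merge(self, a: int, b: int, members: dict[int, set[int]]) -> float:
        L = self.L
        small, big = (a, b) if len(members[a]) <= len(members[b]) else (b, a)
        lab = 0
        comm = self.comm
        for i in members[small]:
            for j in self.adj[i]:
                if comm[j] == big:
                    lab += 1
        da, db = self.d_s.get(a, 0), self.d_s.get(b, 0)
        return lab / L - ((da + db) / (2 * L)) ** 2 + (da / (2 * L)) ** 2 + (
            db / (2 * L)
        ) ** 2

    def apply_merge(self, a: int, b: int, members: dict[int, set[int]]) -> None:
        lab = 0
        comm = self.comm
        small, big = (a, b) if len(members[a]) <= len(members[b]) else (b, a)
        for i in members[small]:
            for j in self.adj[i]:
                if comm[j] == big:
                    lab += 1
        self.l_s[a] = self.l_s.get(a, 0) + self.l_s.get(b, 0) + lab
        self.d_s[a] = self.d_s.get(a, 0) + self.d_s.get(b, 0)
        self.l_s.pop(b, None)
        self.d_s.pop(b, None)
        for i in members[b]:
            comm[i] = a
        members[a] |= members[b]
        del members[b]


def _propose_split(
    state: _SAState,
    module_nodes: list[int],
    rng: np.random.Generator,
    sweeps: int = 3,
) -> tuple[list[int], list[int], float]:
    """Random bisection of one module refined by greedy sweeps on its
    induced subgraph; returns the two halves and the modularity change of
    the split relative to keeping the module whole."""
    L = state.L
    nodes = module_nodes
    side = rng.integers(0, 2, size=len(nodes))
    pos = {n: t for t, n in enumerate(nodes)}
    inside = [[pos[j] for j in state.adj[n] if j in pos and j != n] for n in nodes]
    deg = [int(state.deg[n]) for n in nodes]
    d1 = sum(d for d, s in zip(deg, side) if s == 0)
    d2 = sum(d for d, s in zip(deg, side) if s == 1)
    l1 = l2 = 0
    for t, nbrs in enumerate(inside):
        for q in nbrs:
            if q > t and side[q] == side[t]:
                if side[t] == 0:
                    l1 += 1
                else:
                    l2 += 1

    ds = d1 + d2
    ls_total = sum(1 for t, nbrs in enumerate(inside) for q in nbrs if q > t)

    def gain(l1, l2, d1, d2):
        return (
            (l1 + l2 - ls_total) / L
            - (d1 / (2 * L)) ** 2
            - (d2 / (2 * L)) ** 2
            + (ds / (2 * L)) ** 2
        )

    for _ in range(sweeps):
        improved = False
        order = rng.permutation(len(nodes))
        for t in order:
            k = deg[t]
            k_same = sum(1 for q in inside[t] if side[q] == side[t])
            k_other = len(inside[t]) - k_same
            if side[t] == 0:
                nl1, nl2 = l1 - k_same, l2 + k_other
                nd1, nd2 = d1 - k, d2 + k
            else:
                nl1, nl2 = l1 + k_other, l2 - k_same
                nd1, nd2 = d1 + k, d2 - k
            if gain(nl1, nl2, nd1, nd2) > gain(l1, l2, d1, d2) + 1e-15:
                side[t] = 1 - side[t]
                l1, l2, d1, d2 = nl1, nl2, nd1, nd2
                improved = True
        if not improved:
            break
    g1 = [n for n, s in zip(nodes, side) if s == 0]
    g2 = [n for n, s in zip(nodes, side) if s == 1]
    return g1, g2, gain(l1, l2, d1, d2)


def _apply_split(state: _SAState, g2: list[int], members: dict[int, set[int]]) -> None:
    old = int(state.comm[g2[0]])
    new = state.next_label
    state.next_label += 1
    g2set = set(g2)
    k_new = sum(int(state.deg[i]) for i in g2)
    l_new = 0
    l_cross = 0
    comm = state.comm
    for i in g2:
        for j in state.adj[i]:
            if j == i:
                continue
            if j in g2set:
                if j > i:
                    l_new += 1
            elif comm[j] == old:
                l_cross += 1
    state.l_s[old] = state.l_s.get(old, 0) - l_new - l_cross
    state.l_s[new] = l_new
    state.d_s[old] = state.d_s.get(old, 0) - k_new
    state.d_s[new] = k_new
    if state.d_s[old] == 0:
        del state.d_s[old]
        state.l_s.pop(old, None)
    for i in g2:
        comm[i] = new
    members[old] -= g2set
    members[new] = g2set
    if not members[old]:
        del members[old]


def _calibrate_t0(state: _SAState, rng: np.random.Generator, n_probe: int = 200) -> float:
    """Temperature at which >=90% of initial single-node proposals are
    accepted: T0 = q90 of positive cost increases / -ln(0.9)."""
    labels = list(state.d_s)
    if len(labels) < 2:
        return 1.0
    n = len(state.comm)
    increases = []
    for _ in range(n_probe):
        i = int(rng.integers(n))
        b = labels[int(rng.integers(len(labels)))]
        d = -state.delta_move(i, b)  # cost change
        if d > 0:
            increases.append(d)
    if not increases:
        return 1.0 / (4 * state.L)
    return float(np.quantile(increases, 0.9)) / -math.log(0.9)


def simulated_annealing(
    network: MetaboliteNetwork | nx.Graph, config: SAConfig | None = None
) -> Partition:
    """Maximize modularity by annealing; seeded and reproducible.

    Starts from the all-singletons partition and returns the best
    partition encountered, never worse than the single-module partition
    (M >= 0).  Module labels are canonicalized to 0..K-1 in order of
    first appearance over sorted node ids.
    """
    config = config or SAConfig()
    g = _as_undirected(network)
    nodes = sorted(g.nodes)
    S = len(nodes)
    if S < 2:
        return Partition(assignment={n: 0 for n in nodes}, modularity=0.0)
    if g.number_of_edges() == 0:
        return Partition(assignment={n: 0 for n in nodes}, modularity=0.0)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [[idx[m] for m in g.neighbors(n)] for n in nodes]
    deg = np.array([g.degree(n) for n in nodes], dtype=np.int64)
    L = g.number_of_edges()
    rng = np.random.default_rng(config.seed)

    state = _SAState(adj, deg, L, np.arange(S, dtype=np.int64))
    members: dict[int, set[int]] = {i: {i} for i in range(S)}
    T = config.T0 if config.T0 is not None else _calibrate_t0(state, rng)
    t_min = T * config.t_min_ratio
    n_i = max(1, int(round(config.f * S * S)))
    n_c = max(1, int(round(config.f * S)))

    current_m = state.mod()
    best_m = current_m
    best_comm = state.comm.copy()
    quiet = 0
    n_temps = 0
    while T > t_min and quiet < config.patience:
        accepted_any = False
        for _ in range(n_i):
            labels = list(state.d_s)
            if len(labels) < 2:
                break
            i = int(rng.integers(S))
            b = labels[int(rng.integers(len(labels)))]
            if b == state.comm[i]:
                continue
            dM = state.delta_move(i, b)
            if dM >= 0 or rng.random() < math.exp(dM / T):
                a = int(state.comm[i])
                state.apply_move(i, b)
                members[int(b)].add(i)
                members[a].discard(i)
                if not members[a]:
                    del members[a]
                current_m += dM
                accepted_any = True
        for _ in range(n_c):
            labels = list(state.d_s)
            if rng.random() < 0.5 and len(labels) >= 2:
                pick = rng.choice(len(labels), size=2, replace=False)
                a, b = int(labels[pick[0]]), int(labels[pick[1]])
                dM = state.delta_merge(a, b, members)
                if dM >= 0 or rng.random() < math.exp(dM / T):
                    state.apply_merge(a, b, members)
                    current_m += dM
                    accepted_any = True
            else:
                splittable = [lab for lab in labels if len(members[lab]) >= 2]
                if not splittable:
                    continue
                lab = int(splittable[int(rng.integers(len(splittable)))])
                g1, g2, dM = _propose_split(state, sorted(members[lab]), rng)
                if not g1 or not g2:
                    continue
                if dM >= 0 or rng.random() < math.exp(dM / T):
                    _apply_split(state, g2, members)
                    current_m += dM
                    accepted_any = True
        if current_m > best_m + 1e-12:
            best_m = current_m
            best_comm = state.comm.copy()
        quiet = 0 if accepted_any else quiet + 1
        T *= config.c
        n_temps += 1
    logger.info(
        "SA finished after %d temperatures: best M = %.4f, %d modules",
        n_temps,
        best_m,
        len(set(best_comm.tolist())),
    )

    if best_m < 0:
        return Partition(assignment={n: 0 for n in nodes}, modularity=0.0)
    relabel: dict[int, int] = {}
    assignment = {}
    for n in nodes:
        c = int(best_comm[idx[n]])
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[n] = relabel[c]
    m_exact = modularity(g, assignment)
    return Partition(assignment=assignment, modularity=m_exact)


# ---------------------------------------------------------------------
# role cartography


def _role_of(z: float, p: float) -> str:
    if z >= HUB_Z:
        a, b = HUB_P_SPLITS
        return "R5" if p <= a else "R6" if p <= b else "R7"
    a, b, c = NONHUB_P_SPLITS
    return "R1" if p <= a else "R2" if p <= b else "R3" if p <= c else "R4"


@dataclass
class RoleTable:
    """Per-node within-module degree z, participation coefficient P and
    role class R1-R7."""

    table: pd.DataFrame  # index node; columns module, z, P, role

    def role_of(self, node: str) -> str:
        return str(self.table.loc[node, "role"])

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.table["role"])


def assign_roles(
    network: MetaboliteNetwork | nx.Graph, partition: Partition | Mapping[str, int]
) -> RoleTable:
    """Compute (z, P) on the undirected projection and assign R1-R7.

    Degenerate cases: a module whose intra-module degrees are all equal
    has sigma = 0 and every member gets z = 0; an isolated node (k = 0)
    gets P = 0 and is a non-hub (role R1).
    """
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    g = _as_undirected(network)
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition misses {len(missing)} nodes, e.g. {missing[0]!r}")
    nodes = sorted(g.nodes)
    within: dict[str, int] = {}
    per_module_links: dict[str, dict[int, int]] = {}
    for n in nodes:
        counts: dict[int, int] = {}
        for m in g.neighbors(n):
            counts[assignment[m]] = counts.get(assignment[m], 0) + 1
        per_module_links[n] = counts
        within[n] = counts.get(assignment[n], 0)
    # z-score of within-module degree, per module (population std)
    z: dict[str, float] = {}
    by_module: dict[int, list[str]] = {}
    for n in nodes:
        by_module.setdefault(assignment[n], []).append(n)
    for s, mem in by_module.items():
        ks = np.array([within[n] for n in mem], dtype=float)
        mu, sigma = ks.mean(), ks.std()
        for n, k in zip(mem, ks):
            z[n] = float((k - mu) / sigma) if sigma > 0 else 0.0
    rows = []
    for n in nodes:
        k = g.degree(n)
        if k == 0:
            p = 0.0
        else:
            p = 1.0 - sum((c / k) ** 2 for c in per_module_links[n].values())
        rows.append(
            {"node": n, "module": assignment[n], "z": z[n], "P": p, "role": _role_of(z[n], p)}
        )
    return RoleTable(table=pd.DataFrame(rows).set_index("node"))


def role_frequency_stability(
    network: MetaboliteNetwork | nx.Graph,
    n_runs: int,
    config: SAConfig | None = None,
) -> pd.DataFrame:
    """Empirical per-node role distribution over repeated SA runs.

    Runs the optimizer ``n_runs`` times with seeds derived from the
    config seed and tabulates, for every node, the fraction of runs in
    which it received each role; rows sum to 1.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    config = config or SAConfig()
    base = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(n_runs)]
    counts: dict[str, dict[str, int]] = {}
    for s in seeds:
        part = simulated_annealing(network, replace(config, seed=s))
        roles = assign_roles(network, part)
        for n, r in roles.roles.items():
            counts.setdefault(n, {})[r] = counts.setdefault(n, {}).get(r, 0) + 1
    frame = pd.DataFrame.from_dict(counts, orient="index").fillna(0.0)
    for r in ROLES:
        if r not in frame.columns:
            frame[r] = 0.0
    frame = frame[list(ROLES)] / n_runs
    frame.index.name = "node"
    return frame.sort_index()


def driver_role_profile(
    role_table: RoleTable,
    frequency_table,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Role composition of driver sets at varying frequency thresholds.

    For each threshold f_dt, restrict to nodes with f_dt <= f_d < 1 and
    report the fraction of each role R1-R7 among them (NaN row when the
    set is empty).  ``frequency_table`` is a
    :class:`netctrl.controllability.DriverFrequencyTable` over the same
    node set as the role table.
    """
    if thresholds is None:
        thresholds = [round(0.1 * k, 1) for k in range(10)]
    roles = role_table.roles
    nodes = set(roles)
    fnodes = set(frequency_table.counts)
    if nodes != fnodes:
        raise ValueError(
            f"node sets differ: {len(nodes - fnodes)} only in roles, "
            f"{len(fnodes - nodes)} only in frequencies"
        )
    rows = []
    for t in thresholds:
        sel = [
            n
            for n in nodes
            if frequency_table.frequency(n) < 1 and float(frequency_table.frequency(n)) >= t
        ]
        row: dict[str, float] = {"f_dt": t, "n_nodes": len(sel)}
        for r in ROLES:
            row[r] = (
                sum(1 for n in sel if roles[n] == r) / len(sel) if sel else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("f_dt")
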