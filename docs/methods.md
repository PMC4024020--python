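# Methods

## Network construction

A reaction list over compartmentalized metabolites `name[compartment]`
is translated into a directed graph: one node per compartment-specific
metabolite, one link `A[x] -> B[y]` per (substrate, product) pair of
each reaction. Choices a reaction list does not determine by itself:

- **Reversible reactions** expand to both directions by default
  (`expand_reversible=False` keeps only the forward links). A reaction
  list rarely states which convention its link counts assume, so both
  are available.
- **Parallel inductions** (two reactions implying the same directed
  pair) collapse to a single link; the full set of inducing reaction
  ids is kept per link so annotations are never lost.
- **Self-loops** (a metabolite on both sides of one reaction) are
  retained and flagged, but excluded from the matching analysis by
  default: a self-loop trivially matches its own node and would mask it
  as a driver, which is at odds with reading links as influence between
  distinct metabolites. `include_self_loops=True` restores them.
- A link "crosses into the cell" when some inducing reaction has a
  substrate in the extracellular compartment (code `e` by default) and
  a product elsewhere.
- A link induced by reactions of different core classes counts once per
  class in the multi-label enrichment counts (default); strict
  unique-class counts are reported alongside, since the mapping from
  reaction classes to link classes is a bookkeeping convention, not a
  fact about the model.

## Driver metabolites

The bipartite transform, maximum matching and unmatched-minus rule are
standard structural controllability. Matching is delegated to
Hopcroft–Karp (networkx); the randomization handle is the insertion
order of nodes and edges, shuffled by a seeded `numpy` generator before
each run — matching size is order-invariant, the matched set is not.
Sampling deduplicates **at the driver-set level**: distinct matchings
often induce identical driver sets, and both counts (distinct matchings
seen, distinct MDMSs kept) are reported. Frequencies f_d divide by the
number of distinct MDMSs retained and are classified with exact integer
arithmetic (`Fraction(count, n)`), so the boundary f_d = 0.6 is decided
exactly, never by float rounding.

When a perfect matching exists the minimum driver set is defined as the
single first node in sorted id order (|MDMS| = max(N − |M*|, 1)); the
exact node classification below still reports every node redundant in
that case, a documented asymmetry of the matching-based definitions.

**Exact node classes.** A minus node with no incident bipartite edge
(in-degree 0 once self-loops are excluded) can never be matched: the
node is a driver in every minimum set (critical). A matched minus node
can be freed exactly when it is reachable from a free minus node in the
orientation where matched edges run plus→minus and free edges
minus→plus (swap along that alternating path preserves the matching
size); then it is a driver in some sets (intermittent), otherwise in
none (redundant). An unmatched non-isolated minus node is always
intermittent. This is linear-time per network and is validated against
exhaustive enumeration of all maximum matchings on graphs of up to 8
nodes in the test suite.

**Control mode.** n_r is the redundant fraction; Δn_r = n_r − n_rᵀ with
the transpose network decides centralized (> 0) vs distributed (< 0).
Δn_r = 0 is reported as `indeterminate` — only the strict inequalities
are defined.

## Link classes

From one arbitrary maximum matching, the two orientations of the
bipartite graph (matched plus→minus / free minus→plus, and the reverse)
make every directed walk from a free node an alternating path, and
every non-trivial strongly connected component an alternating cycle. A
link on such a path or cycle is in some but not all maximum matchings
(ordinary); remaining matched links are critical, remaining free links
redundant. The result is invariant to the matching chosen (checked over
multiple seeds in tests, and against enumeration on small graphs). The
SCC partitions of the two orientations coincide by construction; both
are computed and asserted equal as a cheap internal cross-check.
Self-loops excluded from the matching are their own alternating cycles
and are classified ordinary.

## Modularity and annealing

Modularity is evaluated on the undirected projection (reciprocal link
pairs collapse to one edge, self-loops dropped): the measure and its
role thresholds are defined for undirected graphs, and a directed
metabolic network's reciprocal links mostly encode reversibility rather
than two distinct interactions. L is the undirected edge count.

The annealer minimizes C = −M starting from the all-singletons
partition. Schedule parameters, with defaults:

- `f = 1` — per-temperature move counts n_i = f·S² (single node to an
  existing module) and n_c = f·S (collective: merge two random modules,
  or split one);
- `c = 0.965` — cooling factor, T' = c·T;
- `T0` — calibrated when unset: the 90th percentile of the positive
  cost increases over 200 probe moves, divided by −ln(0.9), so ≈90% of
  initial proposals are accepted;
- stop when T < 1e−4·T0 or after 3 consecutive temperatures without an
  accepted move (the bound on temperatures is ≈ log(1e−4)/log(c) ≈ 258).

A split proposal bisects the module at random and refines the bisection
with up to three greedy sweeps on the induced subgraph before the
Metropolis accept/reject at the current global temperature; a merge
evaluates the exact ΔM from the inter-module edge count. All ΔM are
incremental (O(degree) per proposal) and the final partition's M is
recomputed from scratch as a consistency check. The best partition seen
is returned and is never worse than the single-module partition
(M ≥ 0); ties and degenerate inputs (edgeless or single-node networks)
return the single-module partition with M = 0.

On the bundled benchmarks the annealer recovers two disjoint 10-cliques
(M = 0.5) in ≥ 19/20 seeded runs and planted 4-module networks at
NMI ≥ 0.9; run times are seconds at S ≤ 50. The per-temperature move
budget scales as S², so liver-scale networks (S ≈ 1400) are hours of
compute with `f = 1`; `f` and the stop criterion are the knobs to trade
quality for time there. Weighted modularity is not implemented (no
weights are defined for these networks); `role_frequency_stability`
repeats the optimization over derived seeds to expose which role
assignments are artifacts of annealing stochasticity.

**Roles.** z is the within-module degree z-score (population standard
deviation; σ = 0 ⇒ z = 0 for the whole module), P = 1 − Σ_s (k_is/k_i)²
(isolated nodes: P = 0, non-hub). Thresholds, boundaries inclusive on
the lower class: hub iff z ≥ 2.5; non-hubs split at P = 0.05, 0.62,
0.80 into R1–R4; hubs at P = 0.30, 0.75 into R5–R7.

## Centralities

Betweenness follows the explicit definition B_v = Σ_{s≠v≠t}
σ_st(v)/σ_st over directed shortest paths, unnormalized, endpoints
excluded. The closeness family is implemented in the printed
reciprocal-distance (harmonic) form Σ_i 1/d(·), which is finite on
disconnected networks (unreachable pairs contribute 0); out-closeness
uses d(v,i), in-closeness d(i,v), and plain closeness the undirected
projection. The classical 1/Σd variant is available via
`closeness_variant="classical"` for comparison. D = InD + OutD, so a
self-loop contributes 1 to each.

**Tertiles.** Nodes are sorted by (score, id) and cut at ⌊N/3⌋ and
⌊2N/3⌋; a tie group straddling a cut is kept whole in the lower bin, so
bins are deterministic and sizes differ by at most the tie-group size.
All-equal scores degenerate to one bin (logged). Quantile-with-ties
splitting was the main unstated alternative; rank-based splitting was
chosen because it is reproducible without a tie-breaking randomization.

## Chi-square

χ² = Σ (O_i − E_i)²/E_i with E_i = p_i·ΣO, df = N − 1, compared with
the upper-tail critical value from `scipy.stats.chi2`. Expected
percentages are used **as given**: sums within 0.002 of 1 (or of 100)
are accepted without renormalization, because published worksheets
round percentages (33.3/33.4/33.3; 60.14/14.55/25.3 = 99.99%) and
renormalizing would change the printed statistics. Worksheet-style
printed statistics are themselves sums of per-category terms rounded to
2 d.p., which can differ from the exact statistic in the last digit
(32.374 prints as 15.17 + 0.06 + 17.14 = 32.37); tests assert both the
exact value and the worksheet rounding.

## Synthetic data

`generate_reactions` emulates the structural features the analysis
assumes, not the biochemistry of any real model:

- boundary metabolites (default 2.6% of species, matching a ~36/1360
  critical-driver share) live in the extracellular compartment and occur
  only as substrates, each anchoring one transport reaction, so the
  built network provably contains them as in-degree-0 nodes;
- transport reactions (default 20%) draw substrates from one
  compartment and products from another;
- reaction classes follow a 0.60/0.145/0.255 core-high/core-moderate/
  non-core mix, assigned independently of topology;
- side sizes are truncated-geometric on 1–4 (p = 0.5), mimicking small
  multi-substrate reactions — a harness choice, not a claim about real
  degree distributions;
- 10% of reactions are reversible, except those consuming a boundary
  metabolite (the reverse link would break the boundary property).

Defaults (1360 metabolites, 1826 reactions) produce liver-scale
networks of ≈1340 nodes and ≈6000 links. Because classes and topology
are generated independently, enrichment tests on synthetic models are
honest nulls: passing pipeline tests demonstrates correctness of the
computation, not that synthetic critical links are enriched for any
class. Real models differ in degree heterogeneity, reaction-class/
topology correlation, and compartment structure; conclusions about real
systems require real reaction lists.

`generate_planted_network` draws each ordered pair independently
(p_within / p_between) given planted module labels, for module-recovery
and role benchmarks. All generators are pure functions of (spec, seed).

## Problem sizes in the bundled checks

The test suite and acceptance script run at desk scale: enumeration
oracles up to 8 nodes, sampled identities on 200 planted networks of up
to ~32 nodes, annealing benchmarks at 20–48 nodes, synthetic models of
40–300 metabolites. These sizes make every stochastic check exact or
near-exhaustive; the library itself handles liver-scale inputs (the
matching, link-class and centrality stages are sub-second to seconds at
1400 nodes; annealing at that scale is the one expensive stage, see
above).

## Known limitations

- Stoichiometric coefficients, flux balance and SBML input are out of
  scope; the analysis is purely topological.
- Structural controllability treats all nonzero interactions as free
  parameters; biological constraints (conserved moieties, irreversible
  kinetics) can make a structurally controllable system practically
  uncontrollable.
- The sampled f_d estimator is biased toward driver sets reachable by
  edge-order shuffling; exact frequencies would require unbiased
  sampling over all maximum matchings, which is out of scope.
- Weighted modularity and weighted centralities are not implemented.
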