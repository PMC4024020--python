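import networkx as nx
import numpy as np
import pytest

from netctrl import (
    MetaboliteNetwork,
    PlantedPartitionSpec,
    SAConfig,
    assign_roles,
    driver_role_profile,
    generate_planted_network,
    modularity,
    role_frequency_stability,
    simulated_annealing,
)
from netctrl.controllability import DriverFrequencyTable
from netctrl.modularity_roles import _role_of


class TestModularity:
    def test_single_module_partition_is_zero(self, two_cliques):
        assert modularity(two_cliques, {n: 0 for n in two_cliques.nodes}) == 0.0

    def test_two_triangles_correct_partition(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        part = {n: (0 if n < 3 else 1) for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.5)  # 2*(3/6 - (6/12)^2)

    def test_moving_a_node_across_decreases_m(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        good = {n: (0 if n < 3 else 1) for n in g.nodes}
        worse = {**good, 2: 1}
        assert modularity(g, worse) < modularity(g, good)

    def test_agrees_with_networkx_on_random_partitions(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        for _ in range(5):
            part = {n: int(rng.integers(3)) for n in g.nodes}
            groups = [
                {n for n in g.nodes if part[n] == c} for c in set(part.values())
            ]
            assert modularity(g, part) == pytest.approx(
                nx.community.modularity(g, groups)
            )

    def test_missing_node_rejected(self, two_cliques):
        with pytest.raises(ValueError, match="misses"):
            modularity(two_cliques, {"a0": 0})

    def test_edgeless_network_is_zero(self):
        net = MetaboliteNetwork()
        for n in "abc":
            net.add_node(n)
        assert modularity(net, {n: i for i, n in enumerate("abc")}) == 0.0


class TestSimulatedAnnealing:
    def test_recovers_two_cliques(self, two_cliques):
        part = simulated_annealing(two_cliques, SAConfig(seed=0))
        assert part.modularity == pytest.approx(0.5)
        assert part.n_modules == 2
        groups = part.members()
        assert {frozenset(v) for v in groups.values()} == {
            frozenset(f"a{i}" for i in range(10)),
            frozenset(f"b{i}" for i in range(10)),
        }

    def test_identical_seed_gives_identical_partition(self, two_cliques):
        a = simulated_annealing(two_cliques, SAConfig(seed=5))
        b = simulated_annealing(two_cliques, SAConfig(seed=5))
        assert a.assignment == b.assignment and a.modularity == b.modularity

    def test_planted_partition_recovery_nmi(self):
        from sklearn.metrics import normalized_mutual_info_score

        spec = PlantedPartitionSpec(
            n_modules=4, nodes_per_module=12, p_within=0.5, p_between=0.02, seed=3
        )
        net, labels = generate_planted_network(spec)
        nodes = sorted(labels)
        truth = [labels[n] for n in nodes]
        scores = []
        for s in range(3):
            part = simulated_annealing(net, SAConfig(seed=s))
            scores.append(
                normalized_mutual_info_score(truth, [part.assignment[n] for n in nodes])
            )
        assert np.mean(scores) >= 0.9

    def test_output_never_worse_than_single_module(self):
        # a graph with no community structure still must end with M >= 0
        g = nx.gnp_random_graph(12, 0.5, seed=1)
        part = simulated_annealing(g, SAConfig(seed=2))
        assert part.modularity >= 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SAConfig(c=1.5)
        with pytest.raises(ValueError):
            SAConfig(f=0)
        with pytest.raises(ValueError):
            SAConfig(T0=-1.0)


class TestRoles:
    def test_intra_module_node_is_r1(self, two_cliques):
        part = simulated_annealing(two_cliques, SAConfig(seed=0))
        roles = assign_roles(two_cliques, part)
        assert set(roles.table["role"]) == {"R1"}  # all links within modules
        assert (roles.table["P"] == 0.0).all()
        assert (roles.table["z"] == 0.0).all()  # all within-degrees equal

    def test_even_split_participation(self):
        # hub 'c' with one link into each of two modules and one inside
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("c", "d"), ("d", "e")])
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        roles = assign_roles(g, part)
        assert roles.table.loc["c", "P"] == pytest.approx(0.5)  # 1 - 2*(1/2)^2
        assert roles.table.loc["c", "role"] == "R2"

    @pytest.mark.parametrize(
        "z,p,role",
        [
            (0.0, 0.05, "R1"),  # boundary P = 0.05 inclusive below
            (0.0, 0.051, "R2"),
            (0.0, 0.62, "R2"),
            (0.0, 0.63, "R3"),
            (0.0, 0.80, "R3"),
            (0.0, 0.81, "R4"),
            (2.5, 0.30, "R5"),  # z = 2.5 is already a hub
            (2.5, 0.31, "R6"),
            (2.5, 0.75, "R6"),
            (2.5, 0.76, "R7"),
            (2.49, 0.30, "R2"),
        ],
    )
    def test_role_thresholds(self, z, p, role):
        assert _role_of(z, p) == role

    def test_isolated_node_gets_p_zero_nonhub(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("z")
        roles = assign_roles(g, {"a": 0, "b": 0, "z": 1})
        assert roles.table.loc["z", "P"] == 0.0
        assert roles.table.loc["z", "role"] == "R1"

    def test_participation_bounded_and_monotone_spread(self):
        # spreading the same degree over more modules raises P
        g = nx.star_graph(6)
        p2 = assign_roles(g, {0: 0, 1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 1}).table.loc[0, "P"]
        p3 = assign_roles(g, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 2, 6: 2}).table.loc[0, "P"]
        assert 0 <= p2 <= p3 <= 1


class TestStability:
    def test_unique_optimum_gives_degenerate_distribution(self, two_cliques):
        probs = role_frequency_stability(two_cliques, 5, SAConfig(seed=9))
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs["R1"] == 1.0).all()

    def test_reproducible_for_fixed_seed(self, two_cliques):
        a = role_frequency_stability(two_cliques, 3, SAConfig(seed=4))
        b = role_frequency_stability(two_cliques, 3, SAConfig(seed=4))
        assert a.equals(b)

    def test_too_few_runs_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            role_frequency_stability(two_cliques, 1)


class TestDriverRoleProfile:
    def _tables(self, two_cliques):
        part = simulated_annealing(two_cliques, SAConfig(seed=0))
        roles = assign_roles(two_cliques, part)
        counts = {n: (3 if n.startswith("a") else 1) for n in two_cliques.nodes}
        counts["a0"] = 5  # f_d = 1, excluded from every f_dt window
        freq = DriverFrequencyTable(counts=counts, sample_count=5)
        return roles, freq

    def test_fraction_rows_sum_to_one_or_nan(self, two_cliques):
        roles, freq = self._tables(two_cliques)
        prof = driver_role_profile(roles, freq, thresholds=[0.0, 0.6, 0.9])
        role_cols = [c for c in prof.columns if c.startswith("R")]
        sums = prof[role_cols].sum(axis=1)
        for t, s in sums.items():
            if prof.loc[t, "n_nodes"] > 0:
                assert s == pytest.approx(1.0)

    def test_threshold_window_excludes_critical_nodes(self, two_cliques):
        roles, freq = self._tables(two_cliques)
        prof = driver_role_profile(roles, freq, thresholds=[0.0])
        assert prof.loc[0.0, "n_nodes"] == 19  # a0 has f_d = 1

    def test_mismatched_node_sets_rejected(self, two_cliques):
        roles, freq = self._tables(two_cliques)
        freq.counts.pop("b9")
        with pytest.raises(ValueError, match="node sets differ"):
            driver_role_profile(roles, freq)
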