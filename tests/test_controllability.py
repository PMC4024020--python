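from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from netctrl import (
    MetaboliteNetwork,
    Matching,
    control_mode,
    driver_frequency,
    exact_node_control_class,
    maximum_matching,
    mdms_from_matching,
    sample_mdms,
    to_bipartite,
)
from conftest import random_digraph


class TestBipartiteTransform:
    def test_path_maps_links_to_plus_minus_edges(self, path3):
        bp = to_bipartite(path3)
        assert set(bp.plus_nodes) == set(bp.minus_nodes) == {"a", "b", "c"}
        assert set(bp.edges) == {("a", "b"), ("b", "c")}

    def test_edge_count_matches_link_count(self, fig1):
        assert to_bipartite(fig1).n_edges == fig1.n_links == 7

    def test_empty_link_set(self):
        net = MetaboliteNetwork.from_edges([])
        net.add_node("x")
        assert to_bipartite(net).n_edges == 0

    def test_self_loops_excluded_by_default(self):
        net = MetaboliteNetwork.from_edges([("a", "a"), ("a", "b")])
        assert set(to_bipartite(net).edges) == {("a", "b")}
        assert set(to_bipartite(net, include_self_loops=True).edges) == {
            ("a", "a"),
            ("a", "b"),
        }

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            to_bipartite(MetaboliteNetwork())


class TestMaximumMatching:
    @pytest.mark.parametrize(
        "name,expected_size", [("path3", 2), ("star4", 1), ("cycle3", 3), ("fan5", 3)]
    )
    def test_size_on_fixtures(self, gallery, name, expected_size):
        bp = to_bipartite(gallery[name])
        assert maximum_matching(bp).size == expected_size
        # brute-force cross-check
        assert len(oracles.maximum_matchings(bp.edges)[0]) == expected_size

    def test_size_invariant_to_edge_order(self, gallery):
        for name in ("star4", "fan5", "fig1"):
            bp = to_bipartite(gallery[name])
            sizes = {maximum_matching(bp, seed=s).size for s in range(20)}
            assert len(sizes) == 1

    def test_no_edges_gives_empty_matching(self):
        net = MetaboliteNetwork()
        net.add_node("x")
        assert maximum_matching(to_bipartite(net)).size == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_size_equals_brute_force_on_random_digraphs(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=7, p=0.3)
        bp = to_bipartite(net)
        got = maximum_matching(bp, seed=seed).size
        if bp.n_edges:
            assert got == len(oracles.maximum_matchings(bp.edges)[0])
        else:
            assert got == 0


class TestMDMS:
    def test_path_has_unique_driver(self, path3):
        m = maximum_matching(to_bipartite(path3))
        assert set(mdms_from_matching(path3, m)) == {"a"}

    def test_perfect_matching_falls_back_to_single_driver(self, cycle3):
        m = maximum_matching(to_bipartite(cycle3))
        mdms = mdms_from_matching(cycle3, m)
        assert len(mdms) == 1 and set(mdms) == {"a"}  # first in sorted order

    def test_star_driver_sets_have_size_three_and_contain_hub(self, star4):
        for s in range(5):
            m = maximum_matching(to_bipartite(star4), seed=s)
            mdms = mdms_from_matching(star4, m)
            assert len(mdms) == 3 and "h" in mdms

    def test_non_maximum_matching_rejected(self, path3):
        with pytest.raises(ValueError, match="not maximum"):
            mdms_from_matching(path3, Matching(matched_edges=frozenset()))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mdms_size_identity_on_random_digraphs(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=8, p=0.3)
        m = maximum_matching(to_bipartite(net), seed=seed)
        assert len(mdms_from_matching(net, m)) == max(net.n_nodes - m.size, 1)


class TestSampling:
    def test_star_exhaustive_sampling_finds_all_three_sets(self, star4):
        sample = sample_mdms(star4, 300, seed=0)
        assert {frozenset(s) for s in sample} == oracles.all_mdms(star4)

    def test_path_has_single_mdms(self, path3):
        sample = sample_mdms(path3, 50, seed=0)
        assert len(sample) == 1 and set(sample[0]) == {"a"}
        assert sample.n_distinct_matchings == 1

    def test_fixed_seed_reproducible(self, gallery):
        net = gallery["fan5"]
        a = sample_mdms(net, 40, seed=123)
        b = sample_mdms(net, 40, seed=123)
        assert [set(s) for s in a] == [set(s) for s in b]

    def test_all_samples_share_matching_size(self, fig1):
        sample = sample_mdms(fig1, 60, seed=1)
        assert all(len(s) == len(sample[0]) for s in sample)

    def test_invalid_sample_count(self, path3):
        with pytest.raises(ValueError):
            sample_mdms(path3, 0)


class TestDriverFrequency:
    def test_star_frequencies_match_enumeration(self, star4):
        table = driver_frequency(sample_mdms(star4, 300, seed=0), nodes=star4.nodes)
        assert table.frequency("h") == 1
        for leaf in ("l1", "l2", "l3"):
            assert table.frequency(leaf) == Fraction(2, 3)
        assert table.classes["h"] == "critical"
        assert all(table.classes[l] == "high_frequency" for l in ("l1", "l2", "l3"))

    def test_absent_node_is_low_frequency(self, path3):
        table = driver_frequency(sample_mdms(path3, 10, seed=0), nodes=path3.nodes)
        assert table.frequency("b") == 0 and table.classes["b"] == "low_frequency"

    def test_threshold_boundary_point_six_is_high_frequency(self):
        from netctrl.controllability import DriverFrequencyTable

        t = DriverFrequencyTable(counts={"x": 3, "y": 2}, sample_count=5)
        assert t.classes["x"] == "high_frequency"  # f_d = 0.6 exactly
        assert t.classes["y"] == "low_frequency"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            driver_frequency([])

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_converges_to_enumeration_on_small_graphs(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=6, p=0.35)
        exact = oracles.driver_frequencies(net)
        sample = sample_mdms(net, 400, seed=seed)
        if len(sample) == len(oracles.all_mdms(net)):  # saturated the space
            table = driver_frequency(sample, nodes=net.nodes)
            for n in net.nodes:
                assert table.f_d[n] == pytest.approx(exact[n])


class TestExactNodeClasses:
    def test_path_classes(self, path3):
        assert exact_node_control_class(path3) == {
            "a": "critical",
            "b": "redundant",
            "c": "redundant",
        }

    def test_star_leaves_intermittent(self, star4):
        cls = exact_node_control_class(star4)
        assert cls["h"] == "critical"
        assert all(cls[l] == "intermittent" for l in ("l1", "l2", "l3"))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_enumeration(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=8, p=0.3)
        assert exact_node_control_class(net) == oracles.node_classes(net)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_zero_in_degree_nodes_are_critical_with_fd_one(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=8, p=0.25)
        cls = exact_node_control_class(net)
        sample = sample_mdms(net, 50, seed=seed)
        table = driver_frequency(sample, nodes=net.nodes)
        for n in net.nodes:
            if net.in_degree(n) == 0:
                assert cls[n] == "critical"
                assert table.frequency(n) == 1


class TestControlMode:
    def test_path_is_indeterminate_by_symmetry(self, path3):
        res = control_mode(path3)
        assert res.n_r == res.n_r_T == Fraction(2, 3)
        assert res.delta_n_r == 0 and res.mode == "indeterminate"

    def test_star_is_distributed(self, star4):
        res = control_mode(star4)
        assert res.n_r == 0 and res.n_r_T == Fraction(1, 4)
        assert res.mode == "distributed"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_delta_antisymmetric_under_transpose(self, seed):
        net = random_digraph(np.random.default_rng(seed), n_max=8, p=0.3)
        assert control_mode(net).delta_n_r == -control_mode(net.transpose()).delta_n_r
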