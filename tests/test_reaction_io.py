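import pytest

from netctrl import (
    CompartmentalizedMetabolite,
    MetaboliteNetwork,
    Reaction,
    ReactionParseError,
    build_network,
    link_annotation_table,
    parse_reactions,
    serialize_reactions,
)
from netctrl.synthetic_data import FIG1_REACTIONS


def rxn(rid, subs, prods, **kw):
    return Reaction(
        id=rid,
        substrates=frozenset(CompartmentalizedMetabolite.parse(s) for s in subs),
        products=frozenset(CompartmentalizedMetabolite.parse(p) for p in prods),
        **kw,
    )


class TestParsing:
    def test_three_reaction_toy_model(self):
        rxns = parse_reactions(FIG1_REACTIONS)
        assert len(rxns) == 3
        assert [r.is_transport for r in rxns] == [False, True, False]
        mets = {m.id for r in rxns for m in r.substrates | r.products}
        assert len(mets) == 7

    def test_empty_document(self):
        assert parse_reactions("") == []
        assert parse_reactions("# only a comment\n\n") == []

    def test_cross_compartment_reaction_is_transport(self):
        (r,) = parse_reactions("R1: a[c] -> a[m]")
        assert r.is_transport

    def test_annotations_and_reversibility(self):
        (r,) = parse_reactions("R1: a[c] <-> b[c] ; class=core_high")
        assert r.reversible and r.reaction_class == "core_high"
        (r,) = parse_reactions("R1: a[c] -> b[c] ; rev=1 ; class=non_core")
        assert r.reversible and r.reaction_class == "non_core"
        (r,) = parse_reactions("R1: a[c] -> b[c]")
        assert not r.reversible and r.reaction_class == "unlabeled"

    def test_tabular_dialect(self):
        (r,) = parse_reactions("R9\ta[c],b[c]\tc[m]\tcore_moderate\t1")
        assert {m.id for m in r.substrates} == {"a[c]", "b[c]"}
        assert r.reversible and r.is_transport

    @pytest.mark.parametrize(
        "bad",
        [
            "R1: a -> b[c]",  # missing bracket
            "R1: -> b[c]",  # empty substrate side
            "R1: a[c] ->",  # empty product side
            "R1: a[c] b[c]",  # no arrow
            "R1: a[c] -> b[c]\nR1: c[c] -> d[c]",  # duplicate id
            "R1: a[c] -> b[c] ; weird=1",  # unknown annotation
        ],
    )
    def test_malformed_records_raise_with_line(self, bad):
        with pytest.raises(ReactionParseError, match="line"):
            parse_reactions(bad)

    def test_compartment_extraction(self):
        m = CompartmentalizedMetabolite.parse("glc-DASH-D[e]")
        assert m.base_name == "glc-DASH-D" and m.compartment == "e"
        assert m.id == "glc-DASH-D[e]"


class TestBuildNetwork:
    def test_toy_model_network_has_seven_nodes_and_links(self, fig1):
        assert fig1.n_nodes == 7
        assert set(fig1.links) == {
            ("hgentis[c]", "4mlacac[c]"),
            ("hgentis[c]", "h[c]"),
            ("o2[c]", "4mlacac[c]"),
            ("o2[c]", "h[c]"),
            ("h[c]", "h[m]"),
            ("h[m]", "h2co3[m]"),
            ("hco3[m]", "h2co3[m]"),
        }

    def test_duplicate_pairs_collapse_with_reaction_union(self):
        net = build_network(
            [rxn("R1", ["a[c]"], ["b[c]"]), rxn("R2", ["a[c]"], ["b[c]"])]
        )
        assert net.n_nodes == 2 and net.n_links == 1
        assert net.link_reactions[("a[c]", "b[c]")] == {"R1", "R2"}

    def test_reversible_reaction_expands_both_directions(self):
        net = build_network([rxn("R1", ["a[c]"], ["b[c]"], reversible=True)])
        assert set(net.links) == {("a[c]", "b[c]"), ("b[c]", "a[c]")}
        net = build_network(
            [rxn("R1", ["a[c]"], ["b[c]"], reversible=True)], expand_reversible=False
        )
        assert set(net.links) == {("a[c]", "b[c]")}

    def test_self_loop_retained_and_flagged(self):
        net = build_network([rxn("R1", ["a[c]", "b[c]"], ["a[c]"])])
        assert ("a[c]", "a[c]") in net.links
        assert net.self_loops == [("a[c]", "a[c]")]

    def test_every_reactant_is_a_node(self):
        rxns = parse_reactions(FIG1_REACTIONS)
        net = build_network(rxns)
        for r in rxns:
            for m in r.substrates | r.products:
                assert m.id in net.nodes

    def test_round_trip_serialization(self):
        rxns = parse_reactions(FIG1_REACTIONS)
        again = parse_reactions(serialize_reactions(rxns))
        assert build_network(again) == build_network(rxns)

    def test_link_count_bound_for_irreversible_input(self):
        rxns = parse_reactions(FIG1_REACTIONS)
        net = build_network(rxns)
        bound = sum(len(r.substrates) * len(r.products) for r in rxns)
        assert net.n_links <= bound
        assert net.n_links == bound  # no two reactions share a pair here


class TestEdgelist:
    def test_round_trip(self, star4):
        again = MetaboliteNetwork.from_edgelist(star4.to_edgelist())
        assert again == star4

    def test_bad_column_count(self):
        with pytest.raises(ValueError, match="two columns"):
            MetaboliteNetwork.from_edgelist("a b c\n")


class TestLinkAnnotations:
    def test_transport_link_flagged(self, fig1):
        rxns = parse_reactions(FIG1_REACTIONS)
        ann = link_annotation_table(fig1, rxns)
        assert bool(ann.loc[("h[c]", "h[m]"), "is_transport"])
        assert not bool(ann.loc[("h[m]", "h2co3[m]"), "is_transport"])

    def test_intracellular_link_does_not_cross_into_cell(self, fig1):
        ann = link_annotation_table(fig1, parse_reactions(FIG1_REACTIONS))
        assert not ann["crosses_into_cell"].any()  # no extracellular pool here

    def test_environment_intake_detected(self):
        rxns = parse_reactions("T1: glc[e] -> glc[c]")
        net = build_network(rxns)
        ann = link_annotation_table(net, rxns)
        assert bool(ann.loc[("glc[e]", "glc[c]"), "crosses_into_cell"])

    def test_mixed_class_link_records_both_labels(self):
        rxns = parse_reactions(
            "R1: a[c] -> b[c] ; class=core_high\nR2: a[c] -> b[c] ; class=non_core"
        )
        ann = link_annotation_table(build_network(rxns), rxns)
        assert ann.loc[("a[c]", "b[c]"), "reaction_classes"] == ("core_high", "non_core")

    def test_link_without_inducing_reaction_rejected(self, fig1):
        fig1_copy = MetaboliteNetwork.from_edges(fig1.links)  # loses provenance
        with pytest.raises(ValueError, match="no inducing reaction"):
            link_annotation_table(fig1_copy, parse_reactions(FIG1_REACTIONS))
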