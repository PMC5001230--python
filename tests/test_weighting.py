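"""Compartment scoring and interaction weighting."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from pdmg import weighting
from pdmg.weighting import CompartmentScoreTable

from conftest import graph_from_pairs
from oracles import brute_counts, brute_scores, brute_weights


class TestCountInteractedProteins:
    def test_triangle_hand_count(self, triangle):
        locmap = {"A": {"X"}, "B": {"X"}, "C": {"Y"}}
        assert weighting.count_interacted_proteins(triangle, locmap) == {
            "X": 2, "Y": 1,
        }

    def test_isolated_annotated_protein_does_not_count(self, triangle):
        triangle.add_node("LONER")
        locmap = {"A": {"X"}, "LONER": {"X", "Y"}}
        counts = weighting.count_interacted_proteins(
            triangle, locmap, vocabulary=["X", "Y"]
        )
        assert counts == {"X": 1, "Y": 0}

    def test_star_hand_count(self, star_graph):
        locmap = {n: {"X"} for n in star_graph.nodes()}
        locmap["L1"].add("Y")
        locmap["L2"].add("Y")
        counts = weighting.count_interacted_proteins(star_graph, locmap)
        assert counts == {"X": 5, "Y": 2}


class TestScoreCompartments:
    def test_direct_division(self):
        table = weighting.score_compartments({"X": 4, "Y": 2})
        assert table.scores == {"X": 1.0, "Y": 0.5}
        assert table.largest_compartment == "X"
        assert table.smallest_compartment == "Y"

    def test_single_compartment(self):
        table = weighting.score_compartments({"X": 7})
        assert table.scores == {"X": 1.0}
        assert table.largest_compartment == table.smallest_compartment == "X"

    def test_zero_count_compartments_are_excluded(self):
        table = weighting.score_compartments({"X": 4, "Y": 2, "Z": 0})
        assert set(table.scores) == {"X", "Y"}
        assert table.min_score == 0.5

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no annotated interacted"):
            weighting.score_compartments({"X": 0, "Y": 0})

    def test_ties_break_lexicographically(self):
        table = weighting.score_compartments({"B": 3, "A": 3, "D": 1, "C": 1})
        assert table.largest_compartment == "A"
        assert table.smallest_compartment == "C"


TABLE = CompartmentScoreTable({"X": 1.0, "Y": 0.5, "Z": 0.25}, "X", "Z")


class TestWeightEdges:
    @pytest.mark.parametrize(
        "loc_u, loc_v, expected",
        [
            ({"X", "Y"}, {"Y", "Z"}, 0.5),   # shared {Y}: max of its score
            ({"X", "Y"}, {"X", "Y"}, 1.0),   # shared {X,Y}: max is X
            ({"X"}, set(), 0.25),            # missing annotation: SC(C_N)
            ({"X"}, {"Y"}, 0.25),            # disjoint annotation: same fallback
        ],
    )
    def test_single_edge_weight(self, loc_u, loc_v, expected):
        g = nx.Graph([("U", "V")])
        locmap = {"U": loc_u, "V": loc_v}
        weighted = weighting.weight_edges(g, locmap, TABLE)
        assert weighted["U"]["V"]["weight"] == expected

    def test_unannotated_protein_treated_as_empty(self):
        g = nx.Graph([("U", "V")])
        weighted = weighting.weight_edges(g, {"U": {"X"}}, TABLE)
        assert weighted["U"]["V"]["weight"] == TABLE.min_score

    def test_annotation_monotonicity(self, star_graph):
        """Adding a compartment to a protein never lowers any of its edges."""
        locmap = {"H": {"Z"}, "L1": {"Y"}, "L2": {"X"}, "L3": set(), "L4": {"Z"}}
        before = weighting.weight_edges(star_graph, locmap, TABLE)
        locmap["H"] = {"Z", "X"}
        after = weighting.weight_edges(star_graph, locmap, TABLE)
        for u, v in star_graph.edges():
            assert after[u][v]["weight"] >= before[u][v]["weight"]


pair = st.tuples(st.sampled_from("ABCDEFGHJK"), st.sampled_from("ABCDEFGHJK"))
locmaps = st.dictionaries(
    st.sampled_from("ABCDEFGHJK"),
    st.sets(st.sampled_from(["X", "Y", "Z", "W"]), max_size=4),
    max_size=10,
)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(pairs=st.lists(pair, min_size=1, max_size=25), locmap=locmaps)
def test_weighting_matches_brute_force(pairs, locmap):
    """Counts, scores and weights agree with explicit-loop recomputation."""
    graph = graph_from_pairs(pairs)
    if graph.number_of_edges() == 0:
        return
    vocab = ["X", "Y", "Z", "W"]
    counts = weighting.count_interacted_proteins(graph, locmap, vocab)
    edges = list(graph.edges())
    assert counts == brute_counts(edges, locmap, vocab)
    if not any(counts.values()):
        return
    table = weighting.score_compartments(counts)
    assert table.scores == brute_scores(counts)
    assert max(table.scores.values()) == 1.0
    weighted = weighting.weight_edges(graph, locmap, table)
    expected = brute_weights(edges, locmap, table.scores)
    for u, v in edges:
        w = weighted[u][v]["weight"]
        assert w == expected[frozenset((u, v))]
        assert table.min_score <= w <= 1.0
        shared = locmap.get(u, set()) & locmap.get(v, set()) & set(table.scores)
        if shared:
            assert w >= table.min_score
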