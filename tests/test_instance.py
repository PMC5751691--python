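import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nwsteiner.instance import (
    REQUIRED,
    InstanceParams,
    InteractionRecord,
    InvalidInputError,
    PathwayAnnotation,
    SolutionTree,
    build_instance,
    edge_cost,
    node_weight,
    objective_value,
)

from conftest import make_instance, random_small_instance


@pytest.mark.parametrize(
    "con,alpha,beta,in_pathway,boost,expected",
    [
        (100, 2e6, 2, False, 0.5, 200.0),
        (400, 2e6, 2, True, 0.5, 2e6 / 600**2),
        (1, 7, 1, False, 0.5, 7.0),
    ],
)
def test_edge_cost_formula(con, alpha, beta, in_pathway, boost, expected):
    assert edge_cost(con, alpha, beta, in_pathway, boost) == pytest.approx(expected)


@pytest.mark.parametrize("bad_con", [0, -5])
def test_edge_cost_rejects_nonpositive_confidence(bad_con):
    with pytest.raises(InvalidInputError):
        edge_cost(bad_con, 2e6, 2)


def test_edge_cost_rejects_nonpositive_alpha():
    with pytest.raises(InvalidInputError):
        edge_cost(100, alpha=-1)


@given(
    con=st.floats(1, 1e3),
    factor=st.floats(1.01, 10),
    alpha=st.floats(1, 1e7),
    beta=st.floats(0.5, 3),
)
@settings(max_examples=100, deadline=None)
def test_edge_cost_monotone_in_confidence_and_alpha(con, factor, alpha, beta):
    """Cost strictly decreases with confidence and increases with alpha."""
    assert edge_cost(con * factor, alpha, beta) < edge_cost(con, alpha, beta)
    assert edge_cost(con, alpha * factor, beta) > edge_cost(con, alpha, beta)


@pytest.mark.parametrize(
    "degree,gamma,expected", [(10, 5, -0.5), (5, 5, -1.0), (1, 2, -2.0)]
)
def test_node_weight_nonterminal(degree, gamma, expected):
    assert node_weight("x", degree, gamma, is_terminal=False) == pytest.approx(expected)


def test_node_weight_terminal_is_required_sentinel():
    assert node_weight("t", 3, 5, is_terminal=True) is REQUIRED
    assert node_weight("t", 1, 5, is_terminal=True) is REQUIRED


def test_node_weight_rejects_isolated_vertex():
    with pytest.raises(InvalidInputError):
        node_weight("x", 0, 5, is_terminal=False)


@given(degree=st.integers(1, 1000), gamma=st.floats(0.01, 100))
@settings(max_examples=50, deadline=None)
def test_nonterminal_weight_strictly_negative(degree, gamma):
    assert node_weight("x", degree, gamma, is_terminal=False) < 0


class TestBuildInstance:
    def test_path_instance(self):
        records = [
            InteractionRecord("a", "b", 100),
            InteractionRecord("b", "c", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"c"})
        inst = build_instance(records, ann, InstanceParams(gamma=5))
        assert inst.vertices == {"a", "b", "c"}
        assert inst.terminals == {"a", "c"}
        assert inst.node_weight["b"] == pytest.approx(-5 / 2)

    def test_duplicate_edges_keep_minimum_cost(self):
        records = [
            InteractionRecord("a", "b", 100),
            InteractionRecord("b", "a", 200),  # cheaper: cost decreases with con
            InteractionRecord("b", "c", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"c"})
        inst = build_instance(records, ann)
        assert inst.edges[("a", "b")] == pytest.approx(edge_cost(200))

    def test_self_loops_dropped(self):
        records = [
            InteractionRecord("a", "a", 100),
            InteractionRecord("a", "b", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"b"})
        inst = build_instance(records, ann)
        assert ("a", "a") not in inst.edges
        assert set(inst.edges) == {("a", "b")}

    def test_degrees_taken_on_cleaned_graph(self):
        # b has degree 2 even though (a, b) appears twice in the records
        records = [
            InteractionRecord("a", "b", 100),
            InteractionRecord("a", "b", 150),
            InteractionRecord("b", "c", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"c"})
        inst = build_instance(records, ann, InstanceParams(gamma=5))
        assert inst.node_weight["b"] == pytest.approx(-2.5)

    def test_terminals_spanning_components_is_infeasible(self):
        records = [
            InteractionRecord("a", "b", 100),
            InteractionRecord("c", "d", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"d"})
        with pytest.raises(Exception, match="components"):
            build_instance(records, ann)

    def test_restricts_to_terminal_component(self):
        records = [
            InteractionRecord("a", "b", 100),
            InteractionRecord("c", "d", 100),
        ]
        ann = PathwayAnnotation(sources={"a"}, terminals={"b"})
        inst = build_instance(records, ann)
        assert inst.vertices == {"a", "b"}

    def test_no_terminal_warns_or_errors(self):
        records = [InteractionRecord("a", "b", 100)]
        ann = PathwayAnnotation(sources={"zzz"}, terminals=set())
        with pytest.warns(UserWarning):
            build_instance(records, ann)
        with pytest.raises(Exception):
            build_instance(records, ann, on_no_terminal="error")

    def test_empty_records_rejected(self):
        with pytest.raises(InvalidInputError):
            build_instance([], PathwayAnnotation(sources={"a"}, terminals=set()))

    @pytest.mark.parametrize("seed", range(8))
    def test_generator_output_satisfies_invariants(self, seed):
        inst = random_small_instance(seed)
        inst.validate()
        assert all(c > 0 for c in inst.edges.values())
        assert inst.terminals <= inst.vertices
        for v in inst.vertices - inst.terminals:
            assert inst.node_weight[v] < 0


class TestObjectiveValue:
    def test_single_terminal_no_edges(self):
        inst = make_instance({("t", "x"): 5.0}, {"t"}, {"x": -1.0})
        tree = SolutionTree(vertices={"t"}, edges=set())
        assert objective_value(inst, tree) == 0.0

    def test_path_through_steiner_vertex(self, path_21_25):
        tree = SolutionTree(
            vertices={"t1", "v", "t2"}, edges={("t1", "v"), ("t2", "v")}
        )
        assert objective_value(path_21_25, tree) == pytest.approx(21.0)

    def test_direct_terminal_edge(self, path_21_25):
        tree = SolutionTree(vertices={"t1", "t2"}, edges={("t1", "t2")})
        assert objective_value(path_21_25, tree) == pytest.approx(25.0)

    def test_rejects_non_subgraph(self, path_21_25):
        tree = SolutionTree(vertices={"t1", "zz"}, edges=set())
        with pytest.raises(InvalidInputError):
            objective_value(path_21_25, tree)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_sum(self, seed):
        """Objective equals the independent edge-by-edge, vertex-by-vertex sum."""
        from nwsteiner.gw_solver import solve

        inst = random_small_instance(seed)
        tree = solve(inst, seed=seed)
        expected = sum(inst.edges[e] for e in tree.edges) - sum(
            inst.node_weight[v]
            for v in tree.vertices
            if v not in inst.terminals
        )
        assert objective_value(inst, tree) == pytest.approx(expected)


def test_required_sentinel_is_singleton_and_not_numeric():
    assert REQUIRED is type(REQUIRED)()
    assert not isinstance(REQUIRED, float)
    assert repr(REQUIRED) == "REQUIRED"


def test_annotation_requires_nonempty_union():
    with pytest.raises(InvalidInputError):
        PathwayAnnotation(sources=set(), terminals=set())
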