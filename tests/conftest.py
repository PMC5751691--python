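import networkx as nx
import pytest

from nwsteiner.instance import NWInstance, SolutionTree, build_instance
from nwsteiner.fixtures import synth_instance


def make_instance(edges, terminals, weights):
    """Hand-build a small instance from {(u, v): cost} and {v: weight}."""
    vertices = set()
    for e in edges:
        vertices.update(e)
    return NWInstance(
        vertices=vertices,
        edges=dict(edges),
        node_weight=dict(weights),
        terminals=set(terminals),
    )


@pytest.fixture
def path_21_25():
    """t1-v-t2 (costs 10, 10) plus direct t1-t2 (cost 25), w(v) = -1."""
    return make_instance(
        {("t1", "v"): 10.0, ("t2", "v"): 10.0, ("t1", "t2"): 25.0},
        terminals={"t1", "t2"},
        weights={"v": -1.0},
    )


def random_small_instance(seed, n=9, m=14):
    """A ≤10-vertex instance from the frozen synthetic generator."""
    records, ann = synth_instance(
        n, m, seed=seed, planted_pathway_size=5, n_sources=1, n_terminals=2
    )
    return build_instance(records, ann)


def random_tree(n, seed):
    g = nx.random_labeled_tree(n, seed=seed)
    mapping = {i: f"N{i:03d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    return SolutionTree(vertices=set(g.nodes), edges=set(g.edges))
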