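"""Source-to-terminal betweenness degrees on an identified tree.

Ordinary betweenness centrality assumes signal flows between every pair
of vertices; in a signaling pathway it flows from source proteins
(receptors) to terminal proteins (downstream effectors).  The
betweenness degree therefore counts, for protein m and interaction
e_mn, how many source-terminal pairs (i in S, j in T') have their
unique tree path passing through m (endpoints included) or through
e_mn.  On a tree the path is unique, so the counts are integers and

    B(m) >= B(e_mn)   for every interaction incident to m,

since any path using an incident edge necessarily visits the vertex.

Elements whose betweenness degree strictly exceeds a threshold are
selected as important; the automatic threshold is max(|S|, |T'|)
restricted to the tree, so that no element scoring merely "every pair
through one source" (or one terminal) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Set

import networkx as nx

from .instance import Edge, InvalidInputError, SolutionTree, Vertex, canonical_edge

__all__ = ["BetweennessReport", "betweenness", "select_important"]


@dataclass
class BetweennessReport:
    """Per-protein and per-interaction betweenness degrees and selections."""

    node_B: Dict[Vertex, int]
    edge_B: Dict[Edge, int]
    sources_used: FrozenSet[Vertex]
    terminals_used: FrozenSet[Vertex]
    threshold: int | None = None
    selected_nodes: Set[Vertex] = field(default_factory=set)
    selected_edges: Set[Edge] = field(default_factory=set)

    @property
    def auto_threshold(self) -> int:
        return max(len(self.sources_used), len(self.terminals_used))


def betweenness(
    tree: SolutionTree, sources: Iterable[Vertex], terminals: Iterable[Vertex]
) -> BetweennessReport:
    """Betweenness degrees of every vertex and edge of ``tree``.

    Sources and terminals are intersected with the tree's vertices
    before counting; a protein that is both source and terminal
    contributes its (i, i) pair to the vertex count only.  Counting is
    combinatorial: deleting vertex m (edge e) splits the tree into
    components, and the pairs passing through are exactly those not
    confined to one component.
    """
    tree.validate()
    if not tree.vertices:
        return BetweennessReport({}, {}, frozenset(), frozenset())
    g = tree.to_networkx()
    S = frozenset(sources) & tree.vertices
    T = frozenset(terminals) & tree.vertices
    both = S & T
    # ordered pairs (i, j), i != j, whose path is counted
    n_pairs = len(S) * len(T) - len(both)

    node_B: Dict[Vertex, int] = {}
    for m in tree.vertices:
        h = g.copy()
        h.remove_node(m)
        avoiding = 0
        for comp in nx.connected_components(h):
            avoiding += len(S & comp) * len(T & comp) - len(both & comp)
        node_B[m] = n_pairs - avoiding + (1 if m in both else 0)

    edge_B: Dict[Edge, int] = {}
    for e in tree.edges:
        h = g.copy()
        h.remove_edge(*e)
        side_u = nx.node_connected_component(h, e[0])
        side_v = tree.vertices - side_u
        edge_B[e] = len(S & side_u) * len(T & side_v) + len(S & side_v) * len(
            T & side_u
        )

    return BetweennessReport(
        node_B=node_B, edge_B=edge_B, sources_used=S, terminals_used=T
    )


def select_important(
    report: BetweennessReport, threshold: int | str = "auto"
) -> BetweennessReport:
    """Select elements with betweenness degree strictly above ``threshold``.

    ``"auto"`` uses max(|S ∩ V'|, |T' ∩ V'|).  Selection is strict, so
    elements scoring exactly the threshold are left out.
    """
    if threshold == "auto":
        thr = report.auto_threshold
    else:
        thr = int(threshold)
        if thr < 0:
            raise InvalidInputError(f"threshold must be nonnegative, got {thr}")
    report.threshold = thr
    report.selected_nodes = {v for v, b in report.node_B.items() if b > thr}
    report.selected_edges = {e for e, b in report.edge_B.items() if b > thr}
    return report
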