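"""Ground-truth subnetwork, synthetic instance generator, brute-force oracles.

The module ships the published 29-protein / 28-interaction PI3K/Akt +
MAPK subnetwork together with its 8 source proteins (receptor tyrosine
kinases) and 14 terminal proteins (downstream effectors), plus the
printed betweenness degrees of every protein and interaction.  The
source/terminal labeling is derived: it is the unique 8/14 assignment
that reproduces every printed betweenness value, and a regeneration
test re-verifies this at test time.

It also provides a seeded generator of synthetic PPI-like instances
(scale-free-ish topology, STRING-like experimental confidence scores, a
planted connected pathway with designated sources and terminals) and
exhaustive oracles for the node-weighted Steiner optimum and for
betweenness degrees, used to cross-check the heuristic solver and the
combinatorial betweenness implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np

from .instance import (
    Edge,
    InstanceParams,
    InteractionRecord,
    InvalidInputError,
    NWInstance,
    PathwayAnnotation,
    REQUIRED,
    SolutionTree,
    Vertex,
    canonical_edge,
)
from .pathway_metrics import BetweennessReport

__all__ = [
    "FixtureSubnetwork",
    "DISPLAY_NAMES",
    "load_identified_subnetwork",
    "fixture_as_inputs",
    "synth_instance",
    "brute_force_steiner",
    "brute_force_betweenness",
]

# ASCII-safe canonical identifiers; display map restores Greek typography.
DISPLAY_NAMES: Dict[str, str] = {
    "beta-catenin": "β-catenin",
    "IkBa": "IκBα",
    "NF-kB": "NF-κB",
    "PDGFRa": "PDGFRα",
    "PDGFRb": "PDGFRβ",
}

# 8 receptor tyrosine kinases where the signal enters
_SOURCES = (
    "PDGFRa",
    "PDGFRb",
    "IGF1R",
    "ERBB2",
    "INSRR",
    "FGFR1",
    "FGFR2",
    "HER1",
)

# 14 downstream effectors where the signal ends
_TERMINALS = (
    "p53",
    "RELA",
    "NF-kB",
    "p27",
    "p21",
    "LEF1",
    "TCF7L1",
    "TCF7",
    "TCF7L2",
    "AR",
    "BAD",
    "Caspase9",
    "mTOR",
    "FOXO1",
)

# the 28 identified interactions with their published betweenness degrees
_EDGE_TABLE: Tuple[Tuple[str, str, int], ...] = (
    ("AKT1", "PIK3R1", 112),
    ("AKT1", "MDM2", 64),
    ("p53", "MDM2", 64),
    ("EP300", "p53", 56),
    ("PIK3R1", "HER1", 56),
    ("HER1", "Grb2", 42),
    ("EP300", "beta-catenin", 40),
    ("EP300", "RELA", 16),
    ("PDGFRa", "PIK3R1", 14),
    ("PDGFRb", "PIK3R1", 14),
    ("IGF1R", "PIK3R1", 14),
    ("ERBB2", "Grb2", 14),
    ("PIK3R1", "FGFR1", 14),
    ("Grb2", "INSRR", 14),
    ("Grb2", "FGFR2", 14),
    ("IkBa", "NF-kB", 8),
    ("IkBa", "RELA", 8),
    ("p27", "AKT1", 8),
    ("p21", "AKT1", 8),
    ("LEF1", "beta-catenin", 8),
    ("AKT1", "BAD", 8),
    ("AKT1", "Caspase9", 8),
    ("AKT1", "mTOR", 8),
    ("AKT1", "FOXO1", 8),
    ("TCF7L1", "beta-catenin", 8),
    ("TCF7", "beta-catenin", 8),
    ("beta-catenin", "AR", 8),
    ("beta-catenin", "TCF7L2", 8),
)

# the published betweenness degrees of the 29 proteins
_NODE_TABLE: Dict[str, int] = {
    "AKT1": 112,
    "PIK3R1": 112,
    "p53": 64,
    "MDM2": 64,
    "EP300": 56,
    "HER1": 56,
    "Grb2": 42,
    "beta-catenin": 40,
    "RELA": 16,
    "PDGFRa": 14,
    "PDGFRb": 14,
    "IGF1R": 14,
    "ERBB2": 14,
    "INSRR": 14,
    "FGFR1": 14,
    "FGFR2": 14,
    "IkBa": 8,
    "NF-kB": 8,
    "p27": 8,
    "p21": 8,
    "LEF1": 8,
    "TCF7L1": 8,
    "BAD": 8,
    "Caspase9": 8,
    "TCF7": 8,
    "mTOR": 8,
    "AR": 8,
    "FOXO1": 8,
    "TCF7L2": 8,
}


@dataclass(frozen=True)
class FixtureSubnetwork:
    """The published identified subnetwork with its labeling and degrees."""

    tree: SolutionTree
    sources: FrozenSet[str]
    terminals: FrozenSet[str]
    expected_node_B: Dict[str, int]
    expected_edge_B: Dict[Edge, int]


def load_identified_subnetwork() -> FixtureSubnetwork:
    """The 29-protein, 28-interaction identified tree with S and T'."""
    edges = {canonical_edge(a, b) for a, b, _ in _EDGE_TABLE}
    vertices = set(_NODE_TABLE)
    tree = SolutionTree(vertices=vertices, edges=edges)
    tree.validate()
    return FixtureSubnetwork(
        tree=tree,
        sources=frozenset(_SOURCES),
        terminals=frozenset(_TERMINALS),
        expected_node_B=dict(_NODE_TABLE),
        expected_edge_B={canonical_edge(a, b): B for a, b, B in _EDGE_TABLE},
    )


def fixture_as_inputs(
    con: float = 100.0,
) -> Tuple[List[InteractionRecord], PathwayAnnotation]:
    """The fixture tree as pipeline inputs (edge list + annotation).

    Confidence scores are synthetic placeholders (the published tables
    report betweenness degrees, not STRING scores); they exist so the
    full build/solve/metrics pipeline can run on the fixture unchanged.
    """
    fx = load_identified_subnetwork()
    records = [
        InteractionRecord(a, b, con=con, in_pathway=True) for (a, b) in sorted(fx.tree.edges)
    ]
    annotation = PathwayAnnotation(
        sources=fx.sources,
        terminals=fx.terminals,
        pathway_edges=frozenset(frozenset(e) for e in fx.tree.edges),
    )
    return records, annotation


def synth_instance(
    n_vertices: int,
    n_edges: int,
    score_distribution: Optional[Tuple[float, float]] = None,
    planted_pathway_size: Optional[int] = None,
    seed: int = 0,
    n_sources: Optional[int] = None,
    n_terminals: Optional[int] = None,
) -> Tuple[List[InteractionRecord], PathwayAnnotation]:
    """Generate a synthetic PPI-like instance.

    Topology: a preferential-attachment tree plus degree-biased extra
    edges, giving a connected scale-free-ish graph.  Confidence scores
    are drawn from a clipped normal (default mean 110, sd 25, clipped to
    [30, 400]) so that default-parameter edge costs land around the
    100-300 range typical of experimentally scored interactions.  A
    connected pathway of ``planted_pathway_size`` vertices is planted
    and its edges flagged as pathway members; roughly a third of its
    vertices become sources and a third terminals.
    """
    if n_vertices < 2:
        raise InvalidInputError("need at least 2 vertices")
    if n_edges < n_vertices - 1:
        raise InvalidInputError("need n_edges >= n_vertices - 1 for connectivity")
    if n_edges > n_vertices * (n_vertices - 1) // 2:
        raise InvalidInputError("n_edges exceeds the simple-graph maximum")
    mean_sd = score_distribution or (110.0, 25.0)
    k = planted_pathway_size if planted_pathway_size is not None else max(
        3, n_vertices // 6
    )
    if k < 2 or k > n_vertices:
        raise InvalidInputError("planted pathway size out of range")

    rng = np.random.default_rng(seed)
    width = len(str(n_vertices - 1))
    names = [f"P{i:0{width}d}" for i in range(n_vertices)]

    # preferential-attachment tree
    degree = np.zeros(n_vertices)
    edges: set = set()
    tree_adj: Dict[int, List[int]] = {i: [] for i in range(n_vertices)}
    for i in range(1, n_vertices):
        probs = degree[:i] + 1.0
        j = int(rng.choice(i, p=probs / probs.sum()))
        edges.add((min(i, j), max(i, j)))
        degree[i] += 1
        degree[j] += 1
        tree_adj[i].append(j)
        tree_adj[j].append(i)

    # degree-biased extra edges
    guard = 0
    while len(edges) < n_edges:
        probs = degree + 1.0
        u, v = rng.choice(n_vertices, size=2, p=probs / probs.sum())
        u, v = int(u), int(v)
        if u == v or (min(u, v), max(u, v)) in edges:
            guard += 1
            if guard > 100 * n_edges:
                raise InvalidInputError("could not place the requested extra edges")
            continue
        edges.add((min(u, v), max(u, v)))
        degree[u] += 1
        degree[v] += 1

    # plant a connected pathway: BFS over the spanning tree from a random root
    root = int(rng.integers(n_vertices))
    planted = [root]
    seen = {root}
    for v in planted:
        for u in sorted(tree_adj[v]):
            if u not in seen:
                seen.add(u)
                planted.append(u)
            if len(planted) >= k:
                break
        if len(planted) >= k:
            break
    planted = planted[:k]
    planted_set = set(planted)
    pathway_edges = frozenset(
        frozenset((names[a], names[b]))
        for (a, b) in edges
        if a in planted_set and b in planted_set
    )

    ns = n_sources if n_sources is not None else max(1, k // 3)
    nt = n_terminals if n_terminals is not None else max(1, k // 3)
    if ns + nt > k:
        raise InvalidInputError("more sources+terminals than planted vertices")
    chosen = rng.permutation(planted)
    sources = frozenset(names[int(i)] for i in chosen[:ns])
    terminals = frozenset(names[int(i)] for i in chosen[ns : ns + nt])

    mean, sd = mean_sd
    records = []
    for (a, b) in sorted(edges):
        con = float(np.clip(rng.normal(mean, sd), 30.0, 400.0))
        records.append(
            InteractionRecord(
                names[a],
                names[b],
                con=con,
                in_pathway=frozenset((names[a], names[b])) in pathway_edges,
            )
        )
    annotation = PathwayAnnotation(
        sources=sources, terminals=terminals, pathway_edges=pathway_edges
    )
    return records, annotation


def brute_force_steiner(instance: NWInstance) -> Tuple[SolutionTree, float]:
    """Exact node-weighted Steiner optimum by exhaustive enumeration.

    Enumerates every vertex subset containing the terminals whose
    induced subgraph is connected; the best tree on a fixed vertex set
    is its induced minimum-spanning tree by edge cost.  Refuses
    instances above 12 vertices.
    """
    if len(instance.vertices) > 12:
        raise InvalidInputError("brute-force oracle limited to 12 vertices")
    g = instance.to_networkx()
    T = set(instance.terminals)
    free = sorted(instance.vertices - T, key=str)

    best: Optional[Tuple[float, SolutionTree]] = None
    if not T:
        best = (0.0, SolutionTree(vertices=set(), edges=set()))

    for r in range(len(free) + 1):
        for extra in itertools.combinations(free, r):
            subset = T | set(extra)
            if not subset:
                continue
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(sub, weight="cost")
            cost = sum(d["cost"] for _, _, d in mst.edges(data=True))
            for v in subset:
                w = instance.weight(v)
                if w is not REQUIRED:
                    cost -= w
            if best is None or cost < best[0] - 1e-12:
                tree = SolutionTree(
                    vertices=set(subset),
                    edges={canonical_edge(u, v) for u, v in mst.edges()},
                )
                best = (cost, tree)
    if best is None:
        raise InvalidInputError("no feasible subset: terminals not connectable")
    return best[1], best[0]


def brute_force_betweenness(
    tree: SolutionTree, sources: Iterable[Vertex], terminals: Iterable[Vertex]
) -> BetweennessReport:
    """Betweenness degrees by explicit per-pair path walks (oracle)."""
    tree.validate()
    g = tree.to_networkx()
    S = frozenset(sources) & tree.vertices
    T = frozenset(terminals) & tree.vertices
    node_B = {v: 0 for v in tree.vertices}
    edge_B = {e: 0 for e in tree.edges}
    for i in S:
        for j in T:
            if i == j:
                node_B[i] += 1
                continue
            path = nx.shortest_path(g, i, j)
            for v in path:
                node_B[v] += 1
            for u, v in zip(path, path[1:]):
                edge_B[canonical_edge(u, v)] += 1
    return BetweennessReport(
        node_B=node_B, edge_B=edge_B, sources_used=S, terminals_used=T
    )
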