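"""The node-weighted Steiner instance model.

A node-weighted protein-protein interaction network is an undirected,
connected graph with five element types: vertices (proteins), edges
(interactions), compulsory terminals (proteins that must appear in the
identified subnetwork), positive edge costs (in-confidence of an
interaction), and real node weights (confidence that a protein belongs
to the pathway of interest).

Edge costs come from experimental confidence scores *con* as

    c(i, j) = alpha / con**beta

so that highly confident interactions are cheap to include.  Node
weights of non-terminal proteins are

    w(i) = -gamma / degree(i)

a small penalty that shrinks with connectivity, while compulsory
terminals carry the ``REQUIRED`` sentinel: their inclusion is a hard
constraint, not a finite reward, so no arithmetic is ever performed on
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, List, Mapping, Set, Tuple

import networkx as nx

__all__ = [
    "REQUIRED",
    "InvalidInputError",
    "InfeasibleInstanceError",
    "InteractionRecord",
    "PathwayAnnotation",
    "InstanceParams",
    "NWInstance",
    "SolutionTree",
    "edge_cost",
    "node_weight",
    "build_instance",
    "objective_value",
]

Vertex = Hashable
Edge = Tuple[Vertex, Vertex]


class _Required:
    """Sentinel node weight of a compulsory terminal.

    Stands in for the infinite reward that forces a terminal into every
    solution; formulas must branch on it instead of doing arithmetic.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "REQUIRED"

    def __reduce__(self):
        return (_Required, ())


REQUIRED = _Required()


class InvalidInputError(ValueError):
    """An argument violates an operation's precondition."""


class InfeasibleInstanceError(ValueError):
    """The instance admits no feasible solution (e.g. terminals span components)."""


def canonical_edge(u: Vertex, v: Vertex) -> Edge:
    """Order an undirected edge's endpoints canonically (lexicographic)."""
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass(frozen=True)
class InteractionRecord:
    """One scored protein-protein interaction."""

    protein_a: str
    protein_b: str
    con: float
    in_pathway: bool = False

    def __post_init__(self):
        if self.con <= 0:
            raise InvalidInputError(f"confidence score must be positive, got {self.con}")


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway labelling: source proteins S, terminal proteins T', member edges."""

    sources: FrozenSet[str] = frozenset()
    terminals: FrozenSet[str] = frozenset()
    pathway_edges: FrozenSet[FrozenSet[str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "terminals", frozenset(self.terminals))
        object.__setattr__(
            self, "pathway_edges", frozenset(frozenset(e) for e in self.pathway_edges)
        )
        if not (self.sources | self.terminals):
            raise InvalidInputError("S ∪ T' must be nonempty")
        for name in self.sources | self.terminals:
            if not str(name).strip():
                raise InvalidInputError("blank identifier in annotation")

    @property
    def compulsory(self) -> FrozenSet[str]:
        return self.sources | self.terminals


@dataclass(frozen=True)
class InstanceParams:
    """Generation parameters.

    alpha, beta shape edge costs, gamma scales non-terminal penalties,
    boost is the fractional confidence increase for pathway-member
    interactions (0.5 means +50%).
    """

    alpha: float = 2e6
    beta: float = 2.0
    gamma: float = 5.0
    boost: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise InvalidInputError("alpha, beta, gamma must be positive")
        if self.boost < 0:
            raise InvalidInputError("boost must be nonnegative")


@dataclass
class NWInstance:
    """A node-weighted Steiner instance G = (V, E, w, c) with terminal set T."""

    vertices: Set[Vertex]
    edges: Dict[Edge, float]
    node_weight: Dict[Vertex, object]  # float or REQUIRED
    terminals: Set[Vertex]
    params: InstanceParams = field(default_factory=InstanceParams)

    def __post_init__(self):
        self.edges = {canonical_edge(*e): c for e, c in self.edges.items()}

    def cost(self, u: Vertex, v: Vertex) -> float:
        return self.edges[canonical_edge(u, v)]

    def weight(self, v: Vertex):
        return REQUIRED if v in self.terminals else self.node_weight[v]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (u, v), c in self.edges.items():
            g.add_edge(u, v, cost=c)
        return g

    def degree(self, v: Vertex) -> int:
        return sum(1 for e in self.edges if v in e)

    def neighbors(self, v: Vertex) -> List[Vertex]:
        out = []
        for (a, b) in self.edges:
            if a == v:
                out.append(b)
            elif b == v:
                out.append(a)
        return out

    def validate(self, require_connected: bool = True) -> None:
        for e, c in self.edges.items():
            if c <= 0:
                raise InvalidInputError(f"edge {e} has nonpositive cost {c}")
            if e[0] == e[1]:
                raise InvalidInputError(f"self-loop {e}")
            for end in e:
                if end not in self.vertices:
                    raise InvalidInputError(f"edge endpoint {end} not a vertex")
        if not self.terminals <= self.vertices:
            raise InvalidInputError("terminals must be a subset of vertices")
        for v in self.vertices:
            w = self.weight(v)
            if w is not REQUIRED and not (w == w and abs(w) != float("inf")):
                raise InvalidInputError(f"non-terminal {v} has non-finite weight")
        if require_connected and len(self.vertices) > 1:
            if not nx.is_connected(self.to_networkx()):
                raise InfeasibleInstanceError("instance graph is not connected")

    def copy(self) -> "NWInstance":
        return NWInstance(
            vertices=set(self.vertices),
            edges=dict(self.edges),
            node_weight=dict(self.node_weight),
            terminals=set(self.terminals),
            params=self.params,
        )


@dataclass
class SolutionTree:
    """A connected acyclic subnetwork: the identified tree G' = (V', E')."""

    vertices: Set[Vertex]
    edges: Set[Edge]

    def __post_init__(self):
        self.edges = {canonical_edge(*e) for e in self.edges}

    def validate(self) -> None:
        if not self.vertices:
            if self.edges:
                raise InvalidInputError("edges without vertices")
            return
        for e in self.edges:
            for end in e:
                if end not in self.vertices:
                    raise InvalidInputError(f"edge endpoint {end} not in tree vertices")
        if len(self.edges) != len(self.vertices) - 1:
            raise InvalidInputError(
                f"not a tree: {len(self.vertices)} vertices, {len(self.edges)} edges"
            )
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        if not nx.is_connected(g):
            raise InvalidInputError("tree is not connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g


def edge_cost(
    con: float,
    alpha: float = 2e6,
    beta: float = 2.0,
    in_pathway: bool = False,
    boost: float = 0.5,
) -> float:
    """Transform a confidence score into an edge cost, c = alpha / con**beta.

    Pathway-member interactions get their confidence increased by the
    ``boost`` fraction before the transform (the score is not clamped to
    any nominal maximum).
    """
    if con <= 0:
        raise InvalidInputError(f"confidence score must be positive, got {con}")
    if alpha <= 0 or beta <= 0:
        raise InvalidInputError("alpha and beta must be positive")
    if boost < 0:
        raise InvalidInputError("boost must be nonnegative")
    con_eff = con * (1.0 + boost) if in_pathway else con
    return alpha / con_eff**beta


def node_weight(vertex: Vertex, degree: int, gamma: float, is_terminal: bool):
    """Node weight: REQUIRED for terminals, -gamma/degree otherwise."""
    if is_terminal:
        return REQUIRED
    if degree < 1:
        raise InvalidInputError(f"isolated vertex {vertex!r} (degree 0)")
    if gamma <= 0:
        raise InvalidInputError("gamma must be positive")
    return -gamma / degree


def build_instance(
    records: Iterable[InteractionRecord],
    annotation: PathwayAnnotation,
    params: InstanceParams | None = None,
    on_no_terminal: str = "warn",
) -> NWInstance:
    """Assemble a node-weighted Steiner instance from interaction records.

    Self-loops are dropped; duplicate edges collapse to the minimum cost
    (most confident evidence wins); degrees for the node-weight formula
    are taken on the full cleaned graph.  If the graph is disconnected
    the instance is restricted to the component containing the
    terminals; terminals spanning several components make the instance
    infeasible.
    """
    params = params or InstanceParams()
    records = list(records)
    if not records:
        raise InvalidInputError("no interaction records")
    if on_no_terminal not in ("warn", "error"):
        raise InvalidInputError("on_no_terminal must be 'warn' or 'error'")

    pathway_pairs = annotation.pathway_edges
    edges: Dict[Edge, float] = {}
    for rec in records:
        if rec.protein_a == rec.protein_b:
            continue  # self-loop
        e = canonical_edge(rec.protein_a, rec.protein_b)
        member = rec.in_pathway or frozenset(e) in pathway_pairs
        c = edge_cost(rec.con, params.alpha, params.beta, member, params.boost)
        if e not in edges or c < edges[e]:
            edges[e] = c
    if not edges:
        raise InvalidInputError("all records were self-loops")

    vertices: Set[Vertex] = set()
    for e in edges:
        vertices.update(e)
    terminals = set(annotation.compulsory) & vertices
    if not terminals:
        msg = "no source or terminal protein appears in the interaction network"
        if on_no_terminal == "error":
            raise InfeasibleInstanceError(msg)
        warnings.warn(msg, stacklevel=2)

    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        if terminals:
            holding = [c for c in components if c & terminals]
            if len(holding) > 1:
                raise InfeasibleInstanceError(
                    "compulsory terminals span multiple connected components"
                )
            keep = holding[0]
        else:
            keep = max(components, key=len)
        vertices = set(keep)
        edges = {e: c for e, c in edges.items() if e[0] in keep and e[1] in keep}

    # degrees on the cleaned graph, before any reduction
    degrees: Dict[Vertex, int] = {v: 0 for v in vertices}
    for (u, v) in edges:
        degrees[u] += 1
        degrees[v] += 1
    weights = {
        v: node_weight(v, degrees[v], params.gamma, v in terminals) for v in vertices
    }

    inst = NWInstance(
        vertices=vertices,
        edges=edges,
        node_weight=weights,
        terminals=terminals,
        params=params,
    )
    inst.validate()
    return inst


def objective_value(instance: NWInstance, tree: SolutionTree) -> float:
    """Objective: sum of tree edge costs minus finite weights of included vertices.

    Compulsory terminals contribute zero — their inclusion is enforced,
    so the constant infinite reward is dropped to keep comparisons
    between feasible solutions finite.
    """
    if not tree.vertices <= instance.vertices:
        raise InvalidInputError("tree vertices not a subset of instance vertices")
    for e in tree.edges:
        if e not in instance.edges:
            raise InvalidInputError(f"tree edge {e} not in instance")
    total = sum(instance.edges[e] for e in tree.edges)
    for v in tree.vertices:
        w = instance.weight(v)
        if w is not REQUIRED:
            total -= w
    return total
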