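"""Modified unrooted Goemans-Williamson solver for node-weighted Steiner trees.

The growing phase is a moat-growing scheme with *dynamic edge
splitting*: each edge (i, j) is split into two edge parts ep(i, j) and
ep(j, i) that share the edge cost at ratio 1:(s-1),

    slack{ep(i, j)} = c(i, j) / s          (i < j)
    slack{ep(i, j)} = (s - 1) c(i, j) / s  (i > j)

with i < j taken lexicographically on vertex identifiers.  Every vertex
starts as its own cluster whose slack is its node weight; compulsory
terminals are modelled as clusters that never deactivate (the infinite
reward becomes a hard activity guarantee, so no infinite slack ever
enters the arithmetic).  A cluster with nonpositive slack starts
inactive — this is what lets the scheme run on networks whose
non-terminal weights are negative.

A global clock t_g advances from event to event.  An edge event fires
when an active edge part's slack is exhausted; letting r be the partner
part's remaining slack, the clusters merge when r < mu (the merged
cluster inheriting the *sum* of slacks, possibly nonpositive, in which
case it is born inactive), otherwise the event times are re-split:
evenly when the partner's cluster is active, or pushed to t_g + r when
the partner is frozen.  A cluster event simply deactivates a cluster
whose slack ran out.  The loop ends when at most one active cluster
remains; the merge edges inside the final cluster form the raw tree.

Strong pruning then walks the raw tree from a randomly chosen
compulsory terminal root, cutting every subtree whose accumulated
reward nw cannot pay for its connecting edge:

    keep (i, j) iff c(i, j) <= nw(i),  then  nw(j) += nw(i) - c(i, j)

Terminal-bearing branches carry infinite nw and are never cut.
"""

from __future__ import annotations

import heapq
import itertools
import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .instance import (
    Edge,
    InfeasibleInstanceError,
    InvalidInputError,
    NWInstance,
    REQUIRED,
    SolutionTree,
    Vertex,
    canonical_edge,
)
from .reductions import preprocess as _preprocess

__all__ = ["grow", "strong_prune", "solve", "default_mu"]


def default_mu(instance: NWInstance) -> float:
    """Merge tolerance: one millionth of the mean edge cost."""
    if not instance.edges:
        return 1e-6
    return 1e-6 * (sum(instance.edges.values()) / len(instance.edges))


@dataclass
class EdgePart:
    """One half of a split edge, associated with ``owner`` (slack c/s or (s-1)c/s)."""

    owner: Vertex
    other: Vertex
    event_time: float
    dead: bool = False


@dataclass
class ClusterState:
    """Moat bookkeeping for one cluster (stored at its union-find root)."""

    active: bool
    required: bool
    event_time: float  # time its slack runs out; inf for required clusters
    deact: Optional[float] = None  # deactivation time, set when inactive
    parts: List[Tuple[Vertex, Vertex]] = field(default_factory=list)

    def remaining_slack(self, t_g: float) -> float:
        if self.required:
            return math.inf
        if self.active:
            return self.event_time - t_g
        return self.event_time - self.deact


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        """Attach root b under root a; returns (winner, loser)."""
        self.parent[b] = a
        return a, b


def grow(
    instance: NWInstance,
    s: float = 2.0,
    mu: Optional[float] = None,
    on_event=None,
) -> SolutionTree:
    """Growing phase: return the raw (unpruned) tree of merge edges.

    Parameters
    ----------
    s : edge splitting ratio, >= 1; the part at the lexicographically
        smaller endpoint receives 1/s of the cost.
    mu : merge tolerance; a partner slack below mu triggers the merge
        instead of another re-split (guards against endless re-splitting
        when cluster activity flips).  Defaults to 1e-6 x mean edge cost.
    on_event : optional callback ``(time, kind)`` invoked for every
        processed (non-stale) event, kind in {"edge", "cluster"}.
    """
    if s < 1:
        raise InvalidInputError(f"edge splitting ratio s must be >= 1, got {s}")
    if mu is None:
        mu = default_mu(instance)
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    instance.validate(require_connected=True)

    if not instance.terminals:
        warnings.warn("no compulsory terminals: growing phase returns an empty tree")
        return SolutionTree(vertices=set(), edges=set())

    uf = _UnionFind(instance.vertices)
    clusters: Dict[Vertex, ClusterState] = {}
    parts: Dict[Tuple[Vertex, Vertex], EdgePart] = {}
    heap: List[tuple] = []  # (time, kind_rank, seq); edge events rank 0, cluster 1
    seq = itertools.count()
    t_g = 0.0

    for v in instance.vertices:
        w = instance.weight(v)
        if w is REQUIRED:
            clusters[v] = ClusterState(active=True, required=True, event_time=math.inf)
        elif w > 0:
            clusters[v] = ClusterState(active=True, required=False, event_time=w)
            heapq.heappush(heap, (w, 1, next(seq), "cluster", v))
        else:
            clusters[v] = ClusterState(
                active=False, required=False, event_time=w, deact=0.0
            )

    for (a, b), c in instance.edges.items():
        # canonical order a < b: part at a gets c/s, part at b gets (s-1)c/s
        for owner, other, slack in ((a, b, c / s), (b, a, (s - 1.0) * c / s)):
            part = EdgePart(owner=owner, other=other, event_time=slack)
            parts[(owner, other)] = part
            clusters[owner].parts.append((owner, other))
            if clusters[owner].active:
                heapq.heappush(heap, (slack, 0, next(seq), "edge", (owner, other)))

    active_count = sum(1 for cs in clusters.values() if cs.active)
    raw_edges: List[Edge] = []

    def push_part(key: Tuple[Vertex, Vertex]) -> None:
        p = parts[key]
        heapq.heappush(heap, (p.event_time, 0, next(seq), "edge", key))

    while active_count > 1 and heap:
        time, _, _, kind, payload = heapq.heappop(heap)
        if kind == "cluster":
            root = payload
            cs = clusters.get(root)
            if cs is None or not cs.active or cs.required or cs.event_time != time:
                continue  # stale
            t_g = time
            if on_event is not None:
                on_event(time, "cluster")
            cs.active = False
            cs.deact = t_g
            active_count -= 1
            continue

        key = payload
        p1 = parts[key]
        ra = uf.find(p1.owner)
        ca = clusters[ra]
        if p1.dead or not ca.active or p1.event_time != time:
            continue  # stale
        t_g = time
        if on_event is not None:
            on_event(time, "edge")
        rb = uf.find(p1.other)
        if ra == rb:
            # edge became internal to a cluster: retire both parts
            p1.dead = True
            parts[(p1.other, p1.owner)].dead = True
            continue
        cb = clusters[rb]
        p2 = parts[(p1.other, p1.owner)]
        r = (p2.event_time - t_g) if cb.active else (p2.event_time - cb.deact)

        if r >= mu:
            if cb.active:
                # Case 1: split the remaining slack evenly between the parts
                p1.event_time = t_g + r / 2.0
                p2.event_time = t_g + r / 2.0
                push_part(key)
                push_part((p1.other, p1.owner))
            else:
                # Case 2: assume the partner stays frozen until this edge merges
                p1.event_time = t_g + r
                p2.event_time = cb.deact
                push_part(key)
            continue

        # merge event
        raw_edges.append(canonical_edge(p1.owner, p1.other))
        p1.dead = True
        p2.dead = True
        slack_a = ca.remaining_slack(t_g)
        slack_b = cb.remaining_slack(t_g)
        b_was_active = cb.active
        b_deact = cb.deact
        winner, loser = uf.union(ra, rb)
        del clusters[loser]
        required = ca.required or cb.required
        if required:
            new = ClusterState(active=True, required=True, event_time=math.inf)
        else:
            sl = slack_a + slack_b
            if sl > 0:
                new = ClusterState(active=True, required=False, event_time=t_g + sl)
                heapq.heappush(heap, (t_g + sl, 1, next(seq), "cluster", winner))
            else:
                new = ClusterState(
                    active=False, required=False, event_time=t_g + sl, deact=t_g
                )
        new.parts = ca.parts + cb.parts
        clusters[winner] = new

        if not b_was_active:
            # re-anchor the frozen parts: shift by the time the cluster spent frozen
            shift = t_g - b_deact
            for k in cb.parts:
                pp = parts[k]
                if not pp.dead:
                    pp.event_time += shift
                    if new.active:
                        push_part(k)
        # active A parts keep valid heap entries while new is active; if the
        # merged cluster is inactive they go stale and are skipped on pop
        active_count += (1 if new.active else 0) - 1 - (1 if b_was_active else 0)

    # identify the final cluster: last active, else latest-deactivated
    roots = {uf.find(v) for v in instance.vertices}
    active_roots = [rt for rt in roots if clusters[rt].active]
    if active_roots:
        final = min(active_roots, key=str)
    else:
        final = max(roots, key=lambda rt: (clusters[rt].deact, str(rt)))
    members = {v for v in instance.vertices if uf.find(v) == final}
    tree_edges = {e for e in raw_edges if uf.find(e[0]) == final}
    tree = SolutionTree(vertices=members, edges=tree_edges)
    tree.validate()
    return tree


def strong_prune(raw: SolutionTree, instance: NWInstance, seed: int = 0) -> SolutionTree:
    """Pruning phase: cut subtrees whose reward cannot pay for their edge.

    The root is a compulsory terminal chosen by a seeded RNG.  Each
    non-root vertex i is processed once its whole subtree is settled: if
    c(i, j) > nw(i) the edge to its parent j and the subtree at i are
    removed, otherwise the parent absorbs nw(i) - c(i, j).  Terminals
    hold nw = +inf here, which is safe: only inf - finite and
    inf + finite arise.
    """
    raw.validate()
    term_in_tree = sorted((raw.vertices & instance.terminals), key=str)
    if not term_in_tree:
        raise InvalidInputError("raw tree contains no compulsory terminal")
    rng = random.Random(seed)
    root = rng.choice(term_in_tree)

    # BFS orientation from the root
    parent: Dict[Vertex, Vertex] = {root: root}
    children: Dict[Vertex, List[Vertex]] = {v: [] for v in raw.vertices}
    adj: Dict[Vertex, List[Vertex]] = {v: [] for v in raw.vertices}
    for (u, v) in raw.edges:
        adj[u].append(v)
        adj[v].append(u)
    order = [root]
    for v in order:
        for u in adj[v]:
            if u not in parent:
                parent[u] = v
                children[v].append(u)
                order.append(u)

    nw: Dict[Vertex, float] = {}
    kept: Dict[Vertex, bool] = {}
    for i in reversed(order):  # children before parents
        w = instance.weight(i)
        val = math.inf if w is REQUIRED else float(w)
        for k in children[i]:
            if kept[k]:
                val += nw[k] - instance.cost(k, i)
        nw[i] = val
        kept[i] = (i == root) or instance.cost(i, parent[i]) <= nw[i]

    vertices = set()
    edges = set()
    stack = [root]
    while stack:
        v = stack.pop()
        vertices.add(v)
        for k in children[v]:
            if kept[k]:
                edges.add(canonical_edge(v, k))
                stack.append(k)
    tree = SolutionTree(vertices=vertices, edges=edges)
    tree.validate()
    return tree


def solve(
    instance: NWInstance,
    s: float = 2.0,
    mu: Optional[float] = None,
    seed: int = 0,
    do_preprocess: bool = True,
    single_pass: bool = False,
) -> SolutionTree:
    """Full pipeline: preprocess (optional) -> grow -> strong prune -> reassemble.

    Forced edges recorded by the degree-1 reductions are re-attached in
    reverse forcing order, so the output contains every compulsory
    terminal of the original instance.
    """
    instance.validate(require_connected=True)
    if do_preprocess:
        reduced, ledger = _preprocess(instance, single_pass=single_pass)
    else:
        reduced, ledger = instance.copy(), None

    raw = grow(reduced, s=s, mu=mu)
    if reduced.terminals and raw.vertices:
        tree = strong_prune(raw, reduced, seed=seed)
    else:
        tree = raw

    if ledger is not None:
        for t, u in reversed(list(ledger.contraction_map.items())):
            if u not in tree.vertices:
                # absorbing vertex pruned away: can only happen with no
                # surviving terminals; start the tree from it
                tree.vertices.add(u)
            tree.vertices.add(t)
            tree.edges.add(canonical_edge(t, u))
    tree.validate()
    if not instance.terminals <= tree.vertices:
        raise InfeasibleInstanceError("solver lost a compulsory terminal")
    return tree
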