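"""Degree-1 preprocessing tests for node-weighted Steiner instances.

Two optimum-preserving tests shrink an instance before solving:

* terminal degree-1 test — with at least two compulsory terminals, the
  single edge at a degree-1 terminal is forced into the optimum; the
  terminal is removed and its neighbor inherits terminal status.
* non-terminal degree-1 test — with at least one terminal, a degree-1
  non-terminal i with w(i) <= c(i,j) can never pay for its own edge and
  is deleted together with that edge.

Removals can create new degree-1 vertices, so ``preprocess`` alternates
the tests to a fixpoint by default; ``single_pass=True`` preserves the
literal one-sweep behaviour.  A :class:`ReductionLedger` records forced
edges and removals so a solution of the reduced instance can be
reassembled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .instance import Edge, NWInstance, REQUIRED, Vertex, canonical_edge

__all__ = [
    "ReductionLedger",
    "terminal_degree1_test",
    "nonterminal_degree1_test",
    "preprocess",
]


@dataclass
class ReductionLedger:
    """Audit trail of a preprocessing run.

    ``forced_edges`` are guaranteed in the optimum (in forcing order);
    ``contraction_map`` sends each removed terminal to the vertex that
    absorbed its terminal status; ``promoted_weights`` keeps the finite
    weight a newly promoted terminal had before promotion, which is
    exactly the correction needed to relate reduced and original
    objective values.
    """

    forced_edges: List[Edge] = field(default_factory=list)
    removed_vertices: List[Vertex] = field(default_factory=list)
    removed_edges: List[Edge] = field(default_factory=list)
    contraction_map: Dict[Vertex, Vertex] = field(default_factory=dict)
    promoted_weights: Dict[Vertex, float] = field(default_factory=dict)

    def merge(self, other: "ReductionLedger") -> None:
        self.forced_edges.extend(other.forced_edges)
        self.removed_vertices.extend(other.removed_vertices)
        self.removed_edges.extend(other.removed_edges)
        self.contraction_map.update(other.contraction_map)
        for v, w in other.promoted_weights.items():
            self.promoted_weights.setdefault(v, w)

    def objective_offset(self, forced_costs: Dict[Edge, float]) -> float:
        """Objective(original optimum) - objective(reduced optimum).

        Forced edges add their cost; vertices promoted to terminal stop
        contributing their finite weight in the reduced objective.
        """
        return sum(forced_costs[e] for e in self.forced_edges) - sum(
            self.promoted_weights.values()
        )

    def to_dict(self) -> dict:
        return {
            "forced_edges": [list(e) for e in self.forced_edges],
            "removed_vertices": list(self.removed_vertices),
            "removed_edges": [list(e) for e in self.removed_edges],
            "contraction_map": {str(k): v for k, v in self.contraction_map.items()},
        }


def _remove_vertex(inst: NWInstance, v: Vertex) -> None:
    inst.vertices.discard(v)
    inst.terminals.discard(v)
    inst.node_weight.pop(v, None)
    for e in [e for e in inst.edges if v in e]:
        del inst.edges[e]


def terminal_degree1_test(
    instance: NWInstance, single_pass: bool = False
) -> Tuple[NWInstance, ReductionLedger]:
    """Force the pendant edge of every degree-1 compulsory terminal.

    Applies only while |T| >= 2 (with a single terminal the optimum may
    be that terminal alone, so its edge cannot be forced).  The removed
    terminal's neighbor becomes a terminal, as in standard Steiner
    contraction practice.
    """
    inst = instance.copy()
    ledger = ReductionLedger()
    changed = True
    while changed:
        changed = False
        if len(inst.terminals) < 2:
            break
        for t in sorted(inst.terminals, key=str):
            if len(inst.terminals) < 2:
                break
            nbrs = inst.neighbors(t)
            if len(nbrs) != 1:
                continue
            u = nbrs[0]
            e = canonical_edge(t, u)
            ledger.forced_edges.append(e)
            ledger.removed_vertices.append(t)
            ledger.contraction_map[t] = u
            if u not in inst.terminals:
                ledger.promoted_weights[t] = inst.node_weight[u]
            _remove_vertex(inst, t)
            inst.terminals.add(u)
            inst.node_weight[u] = REQUIRED
            changed = True
        if single_pass:
            break
    return inst, ledger


def nonterminal_degree1_test(
    instance: NWInstance, single_pass: bool = False
) -> Tuple[NWInstance, ReductionLedger]:
    """Delete degree-1 non-terminals whose weight cannot pay for their edge.

    A pendant non-terminal i with neighbor j is removed together with
    edge (i,j) whenever w(i) <= c(i,j), provided at least one terminal
    exists.  Iterates to a fixpoint unless ``single_pass``.
    """
    inst = instance.copy()
    ledger = ReductionLedger()
    if not inst.terminals:
        return inst, ledger
    changed = True
    while changed:
        changed = False
        for v in sorted(inst.vertices - inst.terminals, key=str):
            nbrs = inst.neighbors(v)
            if len(nbrs) != 1:
                continue
            j = nbrs[0]
            e = canonical_edge(v, j)
            if inst.node_weight[v] <= inst.edges[e]:
                ledger.removed_vertices.append(v)
                ledger.removed_edges.append(e)
                _remove_vertex(inst, v)
                changed = True
        if single_pass:
            break
    return inst, ledger


def preprocess(
    instance: NWInstance, single_pass: bool = False
) -> Tuple[NWInstance, ReductionLedger]:
    """Alternate both degree-1 tests until neither changes the instance."""
    inst = instance.copy()
    ledger = ReductionLedger()
    while True:
        before = (len(inst.vertices), len(inst.edges), len(inst.terminals))
        inst, led_t = terminal_degree1_test(inst, single_pass=single_pass)
        ledger.merge(led_t)
        inst, led_n = nonterminal_degree1_test(inst, single_pass=single_pass)
        ledger.merge(led_n)
        if single_pass:
            break
        if (len(inst.vertices), len(inst.edges), len(inst.terminals)) == before:
            break
    return inst, ledger
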