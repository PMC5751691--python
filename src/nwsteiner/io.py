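"""Readers and writers for interaction lists, annotations, instances, trees.

Instances are serialized in an STP-style text dialect: the classic
SteinLib layout (Graph / Terminals sections with 1-based vertex
indices) extended with a ``Names`` section mapping indices to protein
identifiers, a ``NodeWeights`` section (the literal token ``REQUIRED``
marks compulsory terminals), and a ``Parameters`` section carrying the
generation constants.  Floats are written with ``repr`` so a write/read
round trip is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd
import yaml

from .instance import (
    InstanceParams,
    InteractionRecord,
    InvalidInputError,
    NWInstance,
    PathwayAnnotation,
    REQUIRED,
    SolutionTree,
    canonical_edge,
)
from .pathway_metrics import BetweennessReport

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_annotation",
    "write_annotation",
    "write_instance_stp",
    "read_instance_stp",
    "write_tree",
    "read_tree",
    "write_report",
]

_A_NAMES = ("protein_a", "protein1", "protein_1", "a", "source")
_B_NAMES = ("protein_b", "protein2", "protein_2", "b", "target")
_SCORE_NAMES = ("score", "con", "confidence", "experimental_score")


def read_interactions(path: str | Path) -> List[InteractionRecord]:
    """Read a delimited interaction list (tab or comma, header required)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = {c.strip().lower(): c for c in df.columns}

    def pick(candidates: Sequence[str], what: str) -> str:
        for name in candidates:
            if name in cols:
                return cols[name]
        raise InvalidInputError(
            f"no {what} column found (have: {list(df.columns)})"
        )

    a = pick(_A_NAMES, "protein_a")
    b = pick(_B_NAMES, "protein_b")
    s = pick(_SCORE_NAMES, "score")
    return [
        InteractionRecord(str(row[a]).strip(), str(row[b]).strip(), float(row[s]))
        for _, row in df.iterrows()
    ]


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_a", "protein_b", "score"])
        for r in records:
            w.writerow([r.protein_a, r.protein_b, repr(r.con)])


def read_annotation(path: str | Path) -> PathwayAnnotation:
    """Read a YAML/JSON annotation with sources, terminals, pathway_edges."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError("annotation must be a mapping")
    edges = data.get("pathway_edges") or []
    return PathwayAnnotation(
        sources=frozenset(str(x) for x in (data.get("sources") or [])),
        terminals=frozenset(str(x) for x in (data.get("terminals") or [])),
        pathway_edges=frozenset(frozenset(str(x) for x in e) for e in edges),
    )


def write_annotation(annotation: PathwayAnnotation, path: str | Path) -> None:
    data = {
        "sources": sorted(annotation.sources),
        "terminals": sorted(annotation.terminals),
        "pathway_edges": sorted(sorted(e) for e in annotation.pathway_edges),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_instance_stp(instance: NWInstance, path: str | Path, name: str = "instance") -> None:
    order = sorted(instance.vertices, key=str)
    index = {v: i + 1 for i, v in enumerate(order)}
    p = instance.params
    lines = [
        '33D32945 STP File, STP Format Version 1.0',
        "SECTION Comment",
        f'Name "{name}"',
        'Creator "nwsteiner"',
        "END",
        "",
        "SECTION Parameters",
        f"Alpha {p.alpha!r}",
        f"Beta {p.beta!r}",
        f"Gamma {p.gamma!r}",
        f"Boost {p.boost!r}",
        "END",
        "",
        "SECTION Graph",
        f"Nodes {len(order)}",
        f"Edges {len(instance.edges)}",
    ]
    for (u, v), c in sorted(instance.edges.items()):
        lines.append(f"E {index[u]} {index[v]} {c!r}")
    lines += ["END", "", "SECTION Names"]
    for v in order:
        lines.append(f"N {index[v]} {v}")
    lines += ["END", "", "SECTION Terminals", f"Terminals {len(instance.terminals)}"]
    for t in sorted(instance.terminals, key=str):
        lines.append(f"T {index[t]}")
    lines += ["END", "", "SECTION NodeWeights"]
    for v in order:
        w = instance.weight(v)
        lines.append(f"NW {index[v]} {'REQUIRED' if w is REQUIRED else repr(w)}")
    lines += ["END", "", "EOF", ""]
    Path(path).write_text("\n".join(lines))


def read_instance_stp(path: str | Path) -> NWInstance:
    text = Path(path).read_text().splitlines()
    section = None
    names: Dict[int, str] = {}
    edges_raw: List[Tuple[int, int, float]] = []
    terminals_raw: List[int] = []
    weights_raw: Dict[int, object] = {}
    params_raw: Dict[str, float] = {}
    n_nodes = 0
    for line in text:
        line = line.strip()
        if not line or line.startswith("33D32945"):
            continue
        toks = line.split()
        if toks[0] == "SECTION":
            section = toks[1]
            continue
        if toks[0] in ("END", "EOF"):
            section = None
            continue
        if section == "Graph":
            if toks[0] == "Nodes":
                n_nodes = int(toks[1])
            elif toks[0] == "E":
                edges_raw.append((int(toks[1]), int(toks[2]), float(toks[3])))
        elif section == "Names" and toks[0] == "N":
            names[int(toks[1])] = " ".join(toks[2:])
        elif section == "Terminals" and toks[0] == "T":
            terminals_raw.append(int(toks[1]))
        elif section == "NodeWeights" and toks[0] == "NW":
            weights_raw[int(toks[1])] = (
                REQUIRED if toks[2] == "REQUIRED" else float(toks[2])
            )
        elif section == "Parameters" and len(toks) == 2:
            params_raw[toks[0].lower()] = float(toks[1])
    if not names:
        names = {i: str(i) for i in range(1, n_nodes + 1)}
    params = InstanceParams(**params_raw) if params_raw else InstanceParams()
    vertices = set(names.values())
    terminals = {names[i] for i in terminals_raw}
    node_weight = {names[i]: w for i, w in weights_raw.items()}
    for t in terminals:
        node_weight.setdefault(t, REQUIRED)
    inst = NWInstance(
        vertices=vertices,
        edges={canonical_edge(names[i], names[j]): c for i, j, c in edges_raw},
        node_weight=node_weight,
        terminals=terminals,
        params=params,
    )
    inst.validate(require_connected=False)
    return inst


def write_tree(tree: SolutionTree, path: str | Path) -> None:
    lines = ["# nwsteiner solution tree"]
    for v in sorted(tree.vertices, key=str):
        lines.append(f"V\t{v}")
    for (u, v) in sorted(tree.edges):
        lines.append(f"E\t{u}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path: str | Path) -> SolutionTree:
    vertices = set()
    edges = set()
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t")
        if toks[0] == "V":
            vertices.add(toks[1])
        elif toks[0] == "E":
            edges.add(canonical_edge(toks[1], toks[2]))
    return SolutionTree(vertices=vertices, edges=edges)


def write_report(report: BetweennessReport, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write the betweenness tables (element, betweenness, selected flag)."""
    with open(nodes_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein", "betweenness", "selected"])
        for v, b in sorted(report.node_B.items(), key=lambda kv: (-kv[1], str(kv[0]))):
            w.writerow([v, b, int(v in report.selected_nodes)])
    with open(edges_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_1", "protein_2", "betweenness", "selected"])
        for e, b in sorted(report.edge_B.items(), key=lambda kv: (-kv[1], str(kv[0]))):
            w.writerow([e[0], e[1], b, int(e in report.selected_edges)])
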