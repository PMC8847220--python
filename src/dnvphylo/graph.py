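"""Layered nearest-neighbor "natural graph" construction.

Layer 1 links every unit (population) to its closest other unit under
the distance matrix; the weakly connected components of those edges form
groups. Layer 2 links each group to its nearest other group, and so on
until one component remains or the requested layer count is reached.
Group-to-group distance defaults to single linkage (minimum pairwise
member distance), matching the closest-neighbor spirit of layer 1;
"mean" and "centroid"-free alternatives are selectable.

Ties in nearest-neighbor choice are broken by lexicographic label
order, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import LabeledMatrix

GROUP_LINKAGE = ("min", "mean")


@dataclass
class GraphLayer:
    """Edges of one layer and the partition they induce."""

    edges: list[tuple[str, str]]  # (unit/group, its nearest neighbor)
    groups: list[tuple[str, ...]]  # connected components, sorted members


@dataclass
class NaturalGraph:
    units: list[str]
    layers: list[GraphLayer] = field(default_factory=list)

    @property
    def layer1_edges(self) -> list[tuple[str, str]]:
        return self.layers[0].edges

    @property
    def groups(self) -> list[tuple[str, ...]]:
        return self.layers[0].groups

    @property
    def layer2_edges(self) -> list[tuple[str, str]]:
        return self.layers[1].edges if len(self.layers) > 1 else []


def _components(nodes: list[str], edges: list[tuple[str, str]]) -> list[tuple[str, ...]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return sorted(tuple(sorted(c)) for c in comps.values())


def build_natural_graph(
    matrix: LabeledMatrix, layers: int = 2, group_linkage: str = "min"
) -> NaturalGraph:
    """Build the layered closest-neighbor graph from a distance matrix."""
    if len(matrix) < 2:
        raise ValueError("natural graph needs at least 2 units")
    if layers < 1:
        raise ValueError("layers must be >= 1")
    if group_linkage not in GROUP_LINKAGE:
        raise ValueError(f"group_linkage must be one of {GROUP_LINKAGE}")

    graph = NaturalGraph(units=list(matrix.labels))
    idx = {l: i for i, l in enumerate(matrix.labels)}

    def unit_dist(a: str, b: str) -> float:
        return float(matrix.values[idx[a], idx[b]])

    # current partition: each element is a sorted tuple of member units;
    # starts as singletons so layer 1 is plain unit-level nearest neighbors
    partition: list[tuple[str, ...]] = [(u,) for u in matrix.labels]

    def group_dist(ga: tuple[str, ...], gb: tuple[str, ...]) -> float:
        pair = [unit_dist(a, b) for a in ga for b in gb]
        return min(pair) if group_linkage == "min" else float(np.mean(pair))

    def name(g: tuple[str, ...]) -> str:
        return ",".join(g)

    for _ in range(layers):
        if len(partition) < 2:
            break
        edges = []
        for g in partition:
            # ties resolve to the lexicographically smallest group name
            nn = min(
                (h for h in partition if h != g),
                key=lambda h: (group_dist(g, h), name(h)),
            )
            edges.append((name(g), name(nn)))
        comps = _components([name(g) for g in partition], edges)
        new_partition = [
            tuple(sorted(u for member in comp for u in member.split(",")))
            for comp in comps
        ]
        graph.layers.append(GraphLayer(edges=edges, groups=sorted(new_partition)))
        partition = sorted(new_partition)
    return graph


def to_dot(graph: NaturalGraph) -> str:
    """Render the graph in DOT: thin layer-1 edges, thick higher layers."""
    lines = ["graph natural_graph {"]
    for unit in graph.units:
        lines.append(f'  "{unit}";')
    seen = set()
    for depth, layer in enumerate(graph.layers, start=1):
        style = "" if depth == 1 else " [penwidth=3]"
        for a, b in layer.edges:
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            lines.append(f'  "{a}" -- "{b}"{style};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_edge_tsv(graph: NaturalGraph) -> str:
    """Edge list as TSV with a layer column."""
    rows = ["source\ttarget\tlayer"]
    for depth, layer in enumerate(graph.layers, start=1):
        for a, b in layer.edges:
            rows.append(f"{a}\t{b}\t{depth}")
    return "\n".join(rows) + "\n"


def write_graph(graph: NaturalGraph, dot_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(dot_path).write_text(to_dot(graph))
    if tsv_path is not None:
        Path(tsv_path).write_text(to_edge_tsv(graph))
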