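"""Layer assignment (longest path) and properization by dummy vertices.

Layers are the horizontal grid positions of the final drawing: layer 0
is the leftmost column and every DAG edge points from a lower to a
higher layer.  The longest-path rule places each vertex at the length
of the longest source-to-vertex path, which keeps the guide sequence on
strictly increasing layers starting at 0 and pushes every vertex as far
left as its predecessors allow.

A *proper* layering has no edge spanning more than one layer.  Long
edges (span s > 1) are replaced by a chain of s - 1 dummy vertices and
s tight dummy edges; every dummy edge inherits the long edge's
multi-edge tuple set unchanged, so no drawing information is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .cycle_removal import DirectionTuple, LayoutDAG
from .model_io import GmsaError

__all__ = ["Layering", "ProperDAG", "assign_layers", "make_proper", "dummy_id"]


@dataclass
class Layering:
    """Vertex -> layer map produced by the longest-path rule."""

    layer: dict[str, int]

    @property
    def n_layers(self) -> int:
        return max(self.layer.values()) + 1

    def span(self, e: tuple[str, str]) -> int:
        return self.layer[e[1]] - self.layer[e[0]]


@dataclass
class ProperDAG:
    """Properly layered DAG: every edge is tight (span exactly 1).

    ``chain_of`` maps each replaced long edge to its ordered dummy
    chain; ``origin_of`` maps every tight edge back to the original DAG
    edge it belongs to (itself for originally-tight edges).
    """

    layer: dict[str, int]
    edges: set[tuple[str, str]]
    real_vertices: set[str]
    dummy_vertices: set[str] = field(default_factory=set)
    dummy_edges: set[tuple[str, str]] = field(default_factory=set)
    chain_of: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    origin_of: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    epsilon: dict[tuple[str, str], set[DirectionTuple]] = field(default_factory=dict)

    @property
    def vertices(self) -> set[str]:
        return self.real_vertices | self.dummy_vertices

    @property
    def n_layers(self) -> int:
        return max(self.layer.values()) + 1

    def is_inner(self, e: tuple[str, str]) -> bool:
        """Inner edges connect two dummy vertices of one chain."""
        return e[0] in self.dummy_vertices and e[1] in self.dummy_vertices

    def edges_in_gap(self, gap: int) -> list[tuple[str, str]]:
        """Tight edges between layer ``gap`` and layer ``gap + 1``."""
        return sorted(e for e in self.edges if self.layer[e[0]] == gap)


def assign_layers(dag: LayoutDAG) -> Layering:
    """Longest-path layering of a single-source DAG.

    ``layer(v)`` is the number of edges on the longest path from the
    source to ``v``; computed by dynamic programming over a topological
    order.
    """
    g = dag.to_networkx()
    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - guarded upstream
        raise GmsaError("cycle removal left a cycle; cannot layer")
    layer: dict[str, int] = {}
    for v in nx.topological_sort(g):
        preds = list(g.predecessors(v))
        layer[v] = 1 + max(layer[u] for u in preds) if preds else 0
    return Layering(layer=layer)


def dummy_id(edge: tuple[str, str], k: int) -> str:
    """Namespaced dummy vertex id, stable across runs."""
    return f"d:{edge[0]}>{edge[1]}:{k}"


def make_proper(dag: LayoutDAG, layering: Layering) -> ProperDAG:
    """Replace every long edge by a tight dummy chain.

    An edge of span s contributes s - 1 dummy vertices occupying the
    traversed layers; all s dummy edges carry the same multi-edge tuple
    set as the replaced edge, which itself disappears from the map.
    """
    layer = dict(layering.layer)
    proper = ProperDAG(layer=layer, edges=set(), real_vertices=set(dag.vertices))
    for e in sorted(dag.edges):
        u, v = e
        span = layer[v] - layer[u]
        if span < 1:  # pragma: no cover - impossible on a layered DAG
            raise GmsaError(f"edge {e} has span {span} < 1")
        if span == 1:
            proper.edges.add(e)
            proper.origin_of[e] = e
            proper.epsilon[e] = set(dag.epsilon[e])
            continue
        chain = tuple(dummy_id(e, k) for k in range(1, span))
        for k, d in enumerate(chain, start=1):
            proper.dummy_vertices.add(d)
            layer[d] = layer[u] + k
        path = (u,) + chain + (v,)
        for a, b in zip(path, path[1:]):
            proper.edges.add((a, b))
            proper.dummy_edges.add((a, b))
            proper.origin_of[(a, b)] = e
            proper.epsilon[(a, b)] = set(dag.epsilon[e])
        proper.chain_of[e] = chain
    return proper
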