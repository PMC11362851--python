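"""Cycle removal by bypath insertion.

A gMSA graph is usually cyclic: two contigs visiting the same pair of
blocks in opposite orders already close a cycle.  Classical feedback-arc
heuristics (Eades-style greedy orderings, DFS back-edge reversal)
minimize the number of reversed edges but may create artificial sources
or sinks, which would be laid out at the far left/right and break the
guide-anchored reading of the drawing.  This module implements instead
a sequence-aware reversal scheme: the guide sequence is inserted first
in its original direction, then every comparative sequence is split
into *bypaths* — sub-paths whose endpoints are already-processed
vertices and whose interior vertices are new — and each bypath is
inserted whole, either forward or reversed, chosen from the current
reachability between its endpoints.  The result is a DAG whose only
source is the guide's first vertex and whose only sink is the guide's
last vertex.

Bookkeeping maintained incrementally while inserting edges:

* ``sigma`` — successor map: ``sigma[v]`` is the set of processed
  vertices reachable from ``v``;
* ``tau`` — predecessor map: ``tau[v]`` is the set of processed
  vertices that reach ``v``;
* ``epsilon`` — multiple-edge map: each DAG edge carries the set of
  ``(direction, sequence name)`` tuples of the original multi-edges it
  stands for, where ``direction`` is ``"forward"`` if the sequence
  traverses the edge in its DAG orientation and ``"backward"``
  otherwise.  The drawing is reconstructed from ``epsilon``, so the
  reversed edges never need to be flipped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_io import GMSAGraph, GmsaError, VertexSequence, require_valid

__all__ = ["DirectionTuple", "Bypath", "LayoutDAG", "decompose_bypaths",
           "add_bypath", "build_dag"]

FORWARD = "forward"
BACKWARD = "backward"

#: One original multi-edge on a DAG edge: (direction w.r.t. the DAG
#: edge, owning sequence name).
DirectionTuple = tuple[str, str]


@dataclass(frozen=True)
class Bypath:
    """A sub-path of a vertex sequence between two processed vertices."""

    vertices: tuple[str, ...]
    sequence: str  # owning sequence name

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise GmsaError(f"bypath of {self.sequence} shorter than 2 vertices")

    @property
    def inner(self) -> tuple[str, ...]:
        return self.vertices[1:-1]


@dataclass
class BypathRecord:
    """How one bypath ended up in the DAG (consumed by later stages)."""

    bypath: Bypath
    reversed: bool
    #: edges newly created for this bypath, in DAG orientation
    new_edges: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class LayoutDAG:
    """Acyclic single-edge graph with successor/predecessor/multi-edge maps."""

    vertices: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    sigma: dict[str, set[str]] = field(default_factory=dict)
    tau: dict[str, set[str]] = field(default_factory=dict)
    epsilon: dict[tuple[str, str], set[DirectionTuple]] = field(default_factory=dict)
    records: list[BypathRecord] = field(default_factory=list)
    guide_name: str = ""
    guide_vertices: tuple[str, ...] = ()

    # -- queries ----------------------------------------------------------
    @property
    def source(self) -> str:
        return self.guide_vertices[0]

    @property
    def sink(self) -> str:
        return self.guide_vertices[-1]

    def sources(self) -> set[str]:
        has_in = {v for _, v in self.edges}
        return self.vertices - has_in

    def sinks(self) -> set[str]:
        has_out = {u for u, _ in self.edges}
        return self.vertices - has_out

    def out_edges(self, v: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[0] == v]

    def n_tuples(self) -> int:
        return sum(len(t) for t in self.epsilon.values())

    # -- mutation ---------------------------------------------------------
    def _add_vertex(self, v: str) -> None:
        if v not in self.vertices:
            self.vertices.add(v)
            self.sigma[v] = set()
            self.tau[v] = set()

    def _insert_edge(self, u: str, v: str) -> None:
        """Add DAG edge (u, v) and run the four reachability update steps."""
        self._add_vertex(u)
        self._add_vertex(v)
        self.edges.add((u, v))
        self.epsilon.setdefault((u, v), set())
        sigma, tau = self.sigma, self.tau
        # successors: u inherits v and v's successors ...
        sigma[u] |= {v} | sigma[v]
        # ... and propagates to every predecessor of u
        for w in tau[u]:
            if v not in sigma[w]:
                sigma[w] |= sigma[u]
        # predecessors, symmetrically
        tau[v] |= {u} | tau[u]
        for w in sigma[v]:
            if u not in tau[w]:
                tau[w] |= tau[v]

    def to_networkx(self):
        """Single-edge DAG as a :class:`networkx.DiGraph` (debug/oracle use)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.vertices))
        g.add_edges_from(sorted(self.edges))
        return g

    def to_dot(self) -> str:
        """GraphViz dump with the multi-edge annotations."""
        lines = ["digraph layoutdag {", "  rankdir=LR;"]
        for v in sorted(self.vertices):
            lines.append(f'  "{v}";')
        for (u, v) in sorted(self.edges):
            lab = ", ".join(f"{d[0]}:{s}" for d, s in sorted(self.epsilon[(u, v)]))
            lines.append(f'  "{u}" -> "{v}" [label="{lab}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def decompose_bypaths(s: VertexSequence, processed: set[str]) -> list[Bypath]:
    """Split a vertex sequence into bypaths at the processed vertices.

    The sequence's first and last vertices must already be processed
    (the anchoring rule guarantees this once the guide is in).  The
    bypaths partition the adjacencies of ``s``; concatenating them,
    dropping repeated junction vertices, reproduces ``s``.
    """
    v = s.vertices
    if v[0] not in processed or v[-1] not in processed:
        raise GmsaError(f"sequence {s.name} is not anchored on processed vertices")
    out: list[Bypath] = []
    start = 0
    for k in range(1, len(v)):
        if v[k] in processed:
            out.append(Bypath(v[start:k + 1], s.name))
            start = k
    return out


def add_bypath(dag: LayoutDAG, bp: Bypath, strict_otherwise_reverse: bool = False) -> BypathRecord:
    """Insert one bypath into the DAG, choosing its orientation.

    Let ``v0`` and ``vn`` be the bypath's endpoints.  If ``vn`` is
    already a successor of ``v0`` the bypath goes in forward; if ``v0``
    is a successor of ``vn`` it goes in reversed (inserting it forward
    would close a cycle).  When the endpoints are unrelated either
    orientation is safe; the default keeps the original reading
    direction, ``strict_otherwise_reverse=True`` reverses instead.

    For each adjacency, an edge is created only if no edge exists
    between the two vertices in either direction; the multi-edge map
    gains exactly one ``(direction, sequence)`` tuple per adjacency,
    with the direction taken relative to the edge actually present.
    """
    v0, vn = bp.vertices[0], bp.vertices[-1]
    if v0 not in dag.vertices or vn not in dag.vertices:
        raise GmsaError(f"bypath endpoints {v0!r}/{vn!r} not processed")
    for w in bp.inner:
        if w in dag.vertices:
            raise GmsaError(f"bypath inner vertex {w!r} already processed")

    if vn in dag.sigma[v0]:
        rev = False
    elif v0 in dag.sigma[vn]:
        rev = True
    else:
        rev = strict_otherwise_reverse

    rec = BypathRecord(bypath=bp, reversed=rev)
    for a, b in zip(bp.vertices, bp.vertices[1:]):
        u, v = (b, a) if rev else (a, b)  # intended DAG orientation
        if (u, v) in dag.edges:
            edge = (u, v)
        elif (v, u) in dag.edges:
            edge = (v, u)
        else:
            dag._insert_edge(u, v)
            edge = (u, v)
            rec.new_edges.append(edge)
        # direction of the sequence adjacency (a -> b) w.r.t. the edge kept
        direction = FORWARD if edge == (a, b) else BACKWARD
        dag.epsilon[edge].add((direction, bp.sequence))
    dag.records.append(rec)
    return rec


def build_dag(g: GMSAGraph, strict_otherwise_reverse: bool = False) -> LayoutDAG:
    """Turn a validated gMSA graph into a single-source/single-sink DAG.

    The guide sequence is inserted first, all edges forward; then each
    comparative sequence, in genome order, is decomposed into bypaths
    against the current processed set and inserted bypath by bypath,
    left to right.
    """
    require_valid(g, "build_dag")
    guide = g.guide
    dag = LayoutDAG(guide_name=guide.name, guide_vertices=guide.vertices)
    dag._add_vertex(guide.vertices[0])
    for a, b in guide.adjacencies:
        dag._insert_edge(a, b)
        dag.epsilon[(a, b)].add((FORWARD, guide.name))

    for s in g.comparatives:
        for bp in decompose_bypaths(s, dag.vertices):
            add_bypath(dag, bp, strict_otherwise_reverse=strict_otherwise_reverse)
    return dag
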