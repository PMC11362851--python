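"""Crossing reduction by block-set sifting.

Classical global sifting moves *blocks* — single vertices or maximal
dummy chains — one at a time through every vertical position and keeps
the position with the fewest edge crossings.  Moving blocks
independently can tear the vertices of one bypath vertically apart, so
they could no longer be aligned on a single horizontal track.  The
variant implemented here therefore sifts whole *block-sets*: the
ordered run of blocks (inner vertices plus the dummy chains of the
long edges) induced by one bypath, with the guide sequence forming a
block-set of its own.  A block-set occupies at most one block per
layer, hence one global list position per block-set induces a total
order inside every layer.

Because each dummy chain lives inside a single block at a single
position, two inner edges can never invert between adjacent layers:
Type 2 crossings (inner/inner) are impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cycle_removal import LayoutDAG
from .layering import ProperDAG
from .model_io import GmsaError

__all__ = ["Block", "BlockSet", "build_block_sets", "derive_vertex_order",
           "count_crossings", "count_type2_crossings", "global_sift"]


@dataclass(frozen=True)
class Block:
    """A single real vertex or one maximal chain of adjacent dummies."""

    members: tuple[str, ...]
    layers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.layers):
            raise GmsaError("block members/layers length mismatch")

    @property
    def min_layer(self) -> int:
        return self.layers[0]

    @property
    def max_layer(self) -> int:
        return self.layers[-1]


@dataclass
class BlockSet:
    """Ordered run of blocks born from one bypath (or the guide)."""

    origin: str
    blocks: list[Block]
    at_layer: dict[int, str] = field(init=False)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.min_layer)
        self.at_layer = {}
        for b in self.blocks:
            for v, l in zip(b.members, b.layers):
                if l in self.at_layer:
                    raise GmsaError(
                        f"block-set {self.origin}: two elements on layer {l}")
                self.at_layer[l] = v

    @property
    def min_layer(self) -> int:
        return self.blocks[0].min_layer

    @property
    def max_layer(self) -> int:
        return max(b.max_layer for b in self.blocks)

    @property
    def elements(self) -> list[str]:
        return [v for b in self.blocks for v in b.members]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BlockSet({self.origin}, layers {self.min_layer}..{self.max_layer})"


def build_block_sets(proper: ProperDAG, dag: LayoutDAG) -> list[BlockSet]:
    """One block-set per bypath with content, plus one for the guide.

    The guide block-set holds every guide vertex and the dummy chains
    of long guide edges.  A bypath's block-set holds its inner vertices
    and the chains of the long edges it created.  Bypaths that created
    neither (plain length-2 bypaths over tight or shared edges) yield
    no block-set.  Every vertex and dummy is covered exactly once.
    """
    layer = proper.layer

    def vertex_block(v: str) -> Block:
        return Block((v,), (layer[v],))

    def chain_blocks(edges: list[tuple[str, str]]) -> list[Block]:
        out = []
        for e in edges:
            chain = proper.chain_of.get(e)
            if chain:
                out.append(Block(chain, tuple(layer[d] for d in chain)))
        return out

    guide_edges = list(zip(dag.guide_vertices, dag.guide_vertices[1:]))
    guide_blocks = [vertex_block(v) for v in dag.guide_vertices]
    guide_blocks += chain_blocks(guide_edges)
    sets = [BlockSet(origin=dag.guide_name, blocks=guide_blocks)]

    for k, rec in enumerate(dag.records):
        blocks = [vertex_block(v) for v in rec.bypath.inner]
        blocks += chain_blocks(rec.new_edges)
        if blocks:
            sets.append(BlockSet(origin=f"{rec.bypath.sequence}#{k}", blocks=blocks))

    covered = [v for bs in sets for v in bs.elements]
    if len(covered) != len(set(covered)) or set(covered) != proper.vertices:
        raise GmsaError("block-sets do not partition the vertices")  # pragma: no cover
    return sets


def derive_vertex_order(order: list[BlockSet], n_layers: int) -> list[list[str]]:
    """Per-layer vertex lists (top to bottom) induced by the block-set order."""
    layers: list[list[str]] = [[] for _ in range(n_layers)]
    for bs in order:
        for l, v in sorted(bs.at_layer.items()):
            layers[l].append(v)
    return layers


def _inversions(seq: list[float]) -> int:
    """Number of strictly-descending pairs, by merge sort."""
    if len(seq) < 2:
        return 0
    mid = len(seq) // 2
    left, right = seq[:mid], seq[mid:]
    inv = _inversions(left) + _inversions(right)
    left.sort()
    right.sort()
    i = j = 0
    merged = []
    while i < len(left) and j < len(right):
        if right[j] < left[i]:
            inv += len(left) - i
            merged.append(right[j])
            j += 1
        else:
            merged.append(left[i])
            i += 1
    seq[:] = merged + left[i:] + right[j:]
    return inv


def count_crossings(order: list[list[str]], proper: ProperDAG) -> int:
    """Exact crossing count of a per-layer vertex order.

    Two edges (u1, v1), (u2, v2) of one layer gap cross iff
    (pos(u1) - pos(u2)) * (pos(v1) - pos(v2)) < 0.  Counted per gap as
    the number of inversions of the target positions after sorting the
    edges by source position.
    """
    pos = [{v: i for i, v in enumerate(lay)} for lay in order]
    total = 0
    for g in range(len(order) - 1):
        ends = sorted((pos[g][u], pos[g + 1][v])
                      for u, v in proper.edges_in_gap(g))
        total += _inversions([float(b) for _, b in ends])
    return total


def count_type2_crossings(order: list[list[str]], proper: ProperDAG) -> int:
    """Crossings between two inner (dummy-chain) edges; must be zero."""
    pos = [{v: i for i, v in enumerate(lay)} for lay in order]
    total = 0
    for g in range(len(order) - 1):
        inner = [e for e in proper.edges_in_gap(g) if proper.is_inner(e)]
        for a in range(len(inner)):
            u1, v1 = inner[a]
            for b in range(a + 1, len(inner)):
                u2, v2 = inner[b]
                if (pos[g][u1] - pos[g][u2]) * (pos[g + 1][v1] - pos[g + 1][v2]) < 0:
                    total += 1
    return total


# ---------------------------------------------------------------------------
# Sifting
# ---------------------------------------------------------------------------

class _SiftContext:
    """Static tables shared by all sifting steps of one graph."""

    def __init__(self, proper: ProperDAG, block_sets: list[BlockSet]):
        self.proper = proper
        self.n_layers = proper.n_layers
        self.gap_edges: list[list[tuple[str, str]]] = [
            proper.edges_in_gap(g) for g in range(self.n_layers - 1)]
        self.owner: dict[str, int] = {}
        for idx, bs in enumerate(block_sets):
            for v in bs.elements:
                self.owner[v] = idx
        # per block-set: incident edges grouped by gap
        self.inc_by_gap: list[dict[int, list[tuple[str, str]]]] = []
        for idx, bs in enumerate(block_sets):
            elems = set(bs.elements)
            by_gap: dict[int, list[tuple[str, str]]] = {}
            for e in proper.edges:
                if e[0] in elems or e[1] in elems:
                    by_gap.setdefault(proper.layer[e[0]], []).append(e)
            self.inc_by_gap.append({g: sorted(es) for g, es in by_gap.items()})


def _sift_step(bs_idx: int, bs: BlockSet, order: list[BlockSet],
               ctx: _SiftContext) -> list[BlockSet]:
    """Move one block-set to its locally best position (topmost on ties).

    Only crossings involving edges incident to the moved block-set can
    change with its position, so candidates are scored on that subset;
    the score of the current position is always among the candidates,
    which makes the full crossing count non-increasing.
    """
    cur_p = order.index(bs)
    others = order[:cur_p] + order[cur_p + 1:]
    elems = set(bs.elements)
    inc = ctx.inc_by_gap[bs_idx]
    gaps = sorted(inc)
    if not gaps:
        return order

    layers_needed = sorted({l for g in gaps for l in (g, g + 1)})
    pos_other: dict[int, dict[str, int]] = {l: {} for l in layers_needed}
    prefix: dict[int, list[int]] = {}
    for l in layers_needed:
        pre = [0]
        for o in others:
            if l in o.at_layer:
                pos_other[l][o.at_layer[l]] = pre[-1]
            pre.append(pre[-1] + (1 if l in o.at_layer else 0))
        prefix[l] = pre

    other_in_gap = {g: [e for e in ctx.gap_edges[g] if e not in set(inc[g])]
                    for g in gaps}

    def score(p: int) -> int:
        s = 0
        for g in gaps:
            pg, pg1 = pos_other[g], pos_other[g + 1]
            off_u = prefix[g][p] - 0.5
            off_v = prefix[g + 1][p] - 0.5

            def pu(w):  # noqa: E306
                return off_u if w in elems else pg[w]

            def pv(w):
                return off_v if w in elems else pg1[w]

            inc_g = inc[g]
            for a, (u1, v1) in enumerate(inc_g):
                x1, y1 = pu(u1), pv(v1)
                for u2, v2 in other_in_gap[g]:
                    if (x1 - pu(u2)) * (y1 - pv(v2)) < 0:
                        s += 1
                for u2, v2 in inc_g[a + 1:]:
                    if (x1 - pu(u2)) * (y1 - pv(v2)) < 0:
                        s += 1
        return s

    best_p, best_s = 0, None
    for p in range(len(others) + 1):
        s = score(p)
        if best_s is None or s < best_s:
            best_p, best_s = p, s
    return others[:best_p] + [bs] + others[best_p:]


def global_sift(block_sets: list[BlockSet], proper: ProperDAG,
                rounds: int = 10) -> tuple[list[BlockSet], list[int]]:
    """Sift every block-set through every position, for up to ``rounds``
    rounds (stopping early once a full round brings no improvement).

    The initial order is the construction order: guide block-set first,
    then bypath block-sets in processing order.  Returns the final
    order together with the full crossing count after each round
    (index 0 = initial count); the counts are non-increasing.
    """
    order = list(block_sets)
    ctx = _SiftContext(proper, block_sets)
    history = [count_crossings(derive_vertex_order(order, proper.n_layers), proper)]
    for _ in range(rounds):
        for idx, bs in enumerate(block_sets):
            order = _sift_step(idx, bs, order, ctx)
        history.append(count_crossings(derive_vertex_order(order, proper.n_layers), proper))
        if history[-1] == history[-2]:
            break
    return order, history
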