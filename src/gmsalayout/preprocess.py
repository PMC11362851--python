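"""Graph normalization before layout.

Three operations prepare a raw gMSA graph for drawing:

* :func:`merge_colinear_blocks` collapses maximal runs of blocks that
  every traversing sequence visits consecutively, in the same order,
  into single merged vertices — the drawing loses no adjacency
  information and gains a lot of horizontal room;
* :func:`trim_to_guide` cuts each comparative sequence back to its
  maximal sub-path anchored on the guide at both ends (loose ends are
  not drawn);
* :func:`extract_range` restricts the guide to a nucleotide window of
  its contig and re-anchors the comparative sequences inside it.
"""

from __future__ import annotations

import logging
from dataclasses import replace

from .model_io import (AlignmentBlock, GMSAGraph, GmsaError, VertexSequence,
                       require_valid)

__all__ = ["merge_colinear_blocks", "trim_to_guide", "extract_range",
           "expand_merged"]

log = logging.getLogger("gmsalayout")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _mergeable_pair(g: GMSAGraph, a: str, b: str) -> bool:
    """True iff the identical set of sequences traverses a then b,
    immediately consecutively, in every one of them."""
    ta, tb = g.traversers(a), g.traversers(b)
    if not ta or ta != tb:
        return False
    for name in ta:
        v = g.sequence(name).vertices
        ia = v.index(a)
        if ia + 1 >= len(v) or v[ia + 1] != b:
            return False
    return True


def _merge_run(g: GMSAGraph, run: list[str]) -> GMSAGraph:
    """Rewrite the graph with ``run`` collapsed into one merged block."""
    parts = [g.blocks[x] for x in run]
    merged = AlignmentBlock(
        id="m:" + "+".join(run),
        rows=tuple(r for b in parts for r in b.rows),
        merged_from=tuple(x for b in parts for x in b.merged_from),
        length_nt=sum(b.length_nt for b in parts),
    )
    drop = set(run)
    blocks = {k: v for k, v in g.blocks.items() if k not in drop}
    blocks[merged.id] = merged
    seqs = []
    for s in g.sequences:
        out: list[str] = []
        for v in s.vertices:
            if v in drop:
                if not out or out[-1] != merged.id:
                    out.append(merged.id)
            else:
                out.append(v)
        seqs.append(replace(s, vertices=tuple(out)))
    return GMSAGraph(blocks=blocks, sequences=seqs)


def merge_colinear_blocks(g: GMSAGraph) -> GMSAGraph:
    """Collapse every maximal co-linear run into a merged vertex.

    A run is collapsible when every sequence touching any of its blocks
    traverses all of them, consecutively and in the same order (the
    strongest reading of "no information is lost": entry and exit
    points stay visible).  Runs are shortened from the right rather
    than collapsing any sequence below the 2-vertex minimum.  The
    operation iterates to a fixpoint and is idempotent.
    """
    require_valid(g, "merge_colinear_blocks")
    changed = True
    while changed:
        changed = False
        order = list(g.guide.vertices) + [
            v for s in g.comparatives for v in s.vertices]
        seen: set[str] = set()
        for start in order:
            if start in seen:
                continue
            seen.add(start)
            run = [start]
            # extend along any one traverser; the pair predicate checks all
            ref = g.sequence(g.traversers(start)[0]).vertices
            k = ref.index(start)
            while k + len(run) < len(ref) and \
                    _mergeable_pair(g, run[-1], ref[k + len(run)]):
                run.append(ref[k + len(run)])
            # never collapse a traversing sequence below 2 vertices
            while len(run) > 1 and any(
                    len(g.sequence(n)) - (len(run) - 1) < 2
                    for n in g.traversers(run[0])):
                run.pop()
            if len(run) > 1:
                g = _merge_run(g, run)
                changed = True
                break
    return g


def expand_merged(g: GMSAGraph, s: VertexSequence) -> tuple[str, ...]:
    """Per-sequence block order with merged vertices expanded again."""
    out: list[str] = []
    for v in s.vertices:
        out.extend(g.blocks[v].merged_from)
    return tuple(out)


# ---------------------------------------------------------------------------
# Trimming and range extraction
# ---------------------------------------------------------------------------

def trim_to_guide(g: GMSAGraph) -> GMSAGraph:
    """Cut comparative sequences to their maximal guide-anchored sub-path.

    Comparative sequences that keep fewer than 2 vertices (including
    those sharing no vertex with the guide) are dropped with a warning.
    """
    guide = g.guide
    guide_set = set(guide.vertices)
    seqs = [guide]
    for s in g.comparatives:
        anchored = [k for k, v in enumerate(s.vertices) if v in guide_set]
        if len(anchored) < 2:
            log.warning("dropping %s: no guide-anchored sub-path of length >= 2",
                        s.name)
            continue
        seqs.append(replace(s, vertices=s.vertices[anchored[0]:anchored[-1] + 1]))
    used = {v for s in seqs for v in s.vertices}
    return GMSAGraph(blocks={k: b for k, b in g.blocks.items() if k in used},
                     sequences=seqs)


def extract_range(g: GMSAGraph, start_nt: int, end_nt: int) -> GMSAGraph:
    """Restrict the guide to the blocks overlapping [start_nt, end_nt]
    (1-based, inclusive on both ends) on the guide contig, then
    re-anchor the comparative sequences inside the window."""
    if start_nt > end_nt:
        raise GmsaError(f"range start {start_nt} > end {end_nt}")
    guide = g.guide

    def overlaps(v: str) -> bool:
        for r in g.blocks[v].rows:
            if r.seq_name == guide.name and r.i <= end_nt and r.j >= start_nt:
                return True
        return False

    kept = tuple(v for v in guide.vertices if overlaps(v))
    if len(kept) < 2:
        raise GmsaError(
            f"range {start_nt}..{end_nt} keeps {len(kept)} guide vertices (< 2)")
    if tuple(v for v in guide.vertices if v in set(kept)) != kept:
        raise GmsaError("range restriction broke the guide order")  # pragma: no cover
    guide_set = set(kept)
    seqs = [replace(guide, vertices=kept)]
    for s in g.comparatives:
        anchored = [k for k, v in enumerate(s.vertices) if v in guide_set]
        if len(anchored) < 2:
            log.warning("dropping %s: outside extracted range", s.name)
            continue
        seqs.append(replace(s, vertices=s.vertices[anchored[0]:anchored[-1] + 1]))
    used = {v for s in seqs for v in s.vertices}
    return GMSAGraph(blocks={k: b for k, b in g.blocks.items() if k in used},
                     sequences=seqs)
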