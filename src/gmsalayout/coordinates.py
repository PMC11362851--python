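"""Vertical coordinate assignment: stacking block-sets onto tracks.

Every block-set gets one integer *track*: the guide sits on track 0,
negative tracks are drawn above it, positive tracks below.  Putting all
vertices of a block-set on one track is what keeps contiguous
sub-sequences horizontally aligned in the drawing.

The sifted block-set order is compacted in two symmetric passes.  The
above-guide pass walks from the block-set just before the guide back to
the top of the list; each block-set is stacked on the closest track
above the guide on which it intersects nothing, where *intersecting*
means overlapping the layer span of a block-set lying between it and
the guide in the sifted order.  (A block-set occupies a contiguous
layer interval, so spans are intervals.)  This preserves the per-layer
relative order of any two block-sets that share a layer, hence the
crossing count of the sifted order is preserved exactly while unused
vertical space collapses.  The below-guide pass mirrors it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_io import GmsaError
from .ordering import BlockSet

__all__ = ["TrackAssignment", "assign_tracks"]


@dataclass
class TrackAssignment:
    """Block-set -> track and vertex -> track maps (guide = 0)."""

    track: dict[str, int]  # keyed by block-set origin
    y: dict[str, int] = field(default_factory=dict)  # vertex -> track

    @property
    def n_tracks(self) -> int:
        return len(set(self.track.values()))

    @property
    def min_track(self) -> int:
        return min(self.track.values())

    @property
    def max_track(self) -> int:
        return max(self.track.values())


def _overlaps(a: BlockSet, b: BlockSet) -> bool:
    return a.min_layer <= b.max_layer and b.min_layer <= a.max_layer


def assign_tracks(ordered: list[BlockSet], index_gs: int) -> TrackAssignment:
    """Stack block-sets as close to the guide as order preservation allows.

    ``ordered`` is the sifted block-set list (top to bottom);
    ``ordered[index_gs]`` is the guide block-set.  Above-guide pass:
    indices ``index_gs - 1 .. 0``; each block-set goes to one track
    beyond the farthest already-placed track among the block-sets whose
    layer span it overlaps (track -1 if it overlaps none).  Below-guide
    pass symmetric.
    """
    if not 0 <= index_gs < len(ordered):
        raise GmsaError(f"guide index {index_gs} out of range")
    ta = TrackAssignment(track={ordered[index_gs].origin: 0})

    placed: list[tuple[BlockSet, int]] = [(ordered[index_gs], 0)]
    for idx in range(index_gs - 1, -1, -1):
        bs = ordered[idx]
        limit = min((t for o, t in placed if _overlaps(bs, o)), default=0)
        ta.track[bs.origin] = limit - 1
        placed.append((bs, limit - 1))

    placed = [(ordered[index_gs], 0)]
    for idx in range(index_gs + 1, len(ordered)):
        bs = ordered[idx]
        limit = max((t for o, t in placed if _overlaps(bs, o)), default=0)
        ta.track[bs.origin] = limit + 1
        placed.append((bs, limit + 1))

    for bs in ordered:
        t = ta.track[bs.origin]
        for v in bs.elements:
            ta.y[v] = t
    return ta
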