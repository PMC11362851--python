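"""Orthogonal multi-edge routing.

After layering, ordering and track assignment, the dummy chains are
collapsed back into single *drawable edges* (the multi-edge map makes
re-reversing unnecessary: every drawable edge knows which original
sequence adjacencies it stands for, and in which direction).  The
original multi-edges are then routed orthogonally:

* parallel edges between the same vertices with the same direction are
  *bundled*; a drawable edge yields at most two bundles (forward and/or
  backward), drawn adjacent to each other;
* bundles attach to the left/right vertex borders only — right border
  for edges departing towards higher layers, left border for edges
  arriving from lower layers — inside an up / straight / down zone
  chosen by the vertical orientation of the first segment;
* every vertical segment gets a unique horizontal slot inside its
  inter-layer gap, separated from its neighbours by the free space
  ``FS``; straight edges need no vertical segment;
* from the stacked connection points and the occupied slots the two
  space parameters *needed vertex height* and *needed inter layer
  space* are derived; the final drawing grows to accommodate them, so
  zones can never overflow.

All coordinates produced here are relative (offsets from vertex
borders and gap edges); the render stage turns them into absolute
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coordinates import TrackAssignment
from .cycle_removal import DirectionTuple, FORWARD
from .layering import ProperDAG
from .model_io import GmsaError

__all__ = ["RoutingConfig", "SpaceParams", "DrawableEdge", "EdgeBundle",
           "Connection", "Slot", "EdgeRoute", "RoutingResult",
           "collapse_dummies", "bundle_edges", "route_edges"]

UP, STRAIGHT, DOWN = "up", "straight", "down"
_ZONES = (UP, STRAIGHT, DOWN)


@dataclass(frozen=True)
class RoutingConfig:
    """Spacing knobs of the orthogonal router (pixels)."""

    fs: float = 4.0            # free space between adjacent edges/slots
    bs_border: float = 6.0     # space between a vertex border / gap edge and the first edge
    member_px: float = 1.0     # line width contributed by one bundled member
    max_bundle_px: float = 6.0  # cap on a bundle's line width
    min_vertex_height: float = 18.0
    min_inter_layer_space: float = 26.0

    def __post_init__(self) -> None:
        for name in ("fs", "bs_border", "member_px", "max_bundle_px"):
            if getattr(self, name) <= 0:
                raise GmsaError(f"routing parameter {name} must be > 0")


@dataclass(frozen=True)
class SpaceParams:
    """The two space parameters consumed by the final drawing."""

    needed_vertex_height: float
    needed_inter_layer_space: float
    fs: float
    bs_border: float


@dataclass(frozen=True)
class DrawableEdge:
    """One former DAG edge, dummies collapsed away.

    ``route_track`` is the track of the dummy chain the long edge ran
    along (``None`` for tight edges); ``span`` the (start, end) layers.
    """

    u: str
    v: str
    tuples: frozenset[DirectionTuple]
    span: tuple[int, int]
    route_track: int | None = None

    @property
    def is_long(self) -> bool:
        return self.span[1] - self.span[0] > 1


@dataclass(frozen=True)
class EdgeBundle:
    """Co-routed parallel members of one direction of a drawable edge."""

    u: str
    v: str
    direction: str
    members: tuple[str, ...]
    width: float
    route_track: int | None
    span: tuple[int, int]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.u, self.v, self.direction)

    @property
    def is_long(self) -> bool:
        return self.span[1] - self.span[0] > 1


@dataclass(frozen=True)
class Connection:
    """A bundle endpoint on a vertex border (relative coordinates).

    ``offset`` is the distance of the slot's line center from the
    vertex top border (zone ``up``), from the vertex vertical midpoint
    (``straight``, may be negative), or from the bottom border
    (``down``), in pixels.
    """

    vertex: str
    side: str  # "L" or "R"
    zone: str
    offset: float
    width: float


@dataclass(frozen=True)
class Slot:
    """A vertical-segment slot inside one inter-layer gap.

    ``offset`` is the distance of the slot center from the left edge of
    the gap.
    """

    gap: int
    bundle_key: tuple[str, str, str]
    kind: str  # "jog" (tight edge), "start" / "end" (long edge)
    width: float
    offset: float


@dataclass
class EdgeRoute:
    """Absolute orthogonal polyline of one bundle (filled in by render)."""

    bundle: EdgeBundle
    polyline: list[tuple[float, float]]

    @property
    def bends(self) -> int:
        return max(0, len(self.polyline) - 2)


@dataclass
class RoutingResult:
    drawables: list[DrawableEdge]
    bundles: list[EdgeBundle]
    #: (bundle key, "u" | "v") -> Connection
    connections: dict[tuple[tuple[str, str, str], str], Connection]
    #: gap index -> slots, left to right
    slots: dict[int, list[Slot]]
    space: SpaceParams
    tracks: TrackAssignment

    def slot_for(self, key: tuple[str, str, str], kind: str) -> Slot | None:
        for slots in self.slots.values():
            for s in slots:
                if s.bundle_key == key and s.kind == kind:
                    return s
        return None


# ---------------------------------------------------------------------------
# Collapsing and bundling
# ---------------------------------------------------------------------------

def collapse_dummies(proper: ProperDAG, tracks: TrackAssignment) -> list[DrawableEdge]:
    """One drawable edge per original DAG edge.

    A dummy chain must carry one uniform tuple set along all its edges
    (properization copies it); its block's track becomes the route
    track of the horizontal run.
    """
    out = []
    originals = sorted(set(proper.origin_of.values()))
    for e in originals:
        u, v = e
        span = (proper.layer[u], proper.layer[v])
        chain = proper.chain_of.get(e)
        if chain is None:
            out.append(DrawableEdge(u, v, frozenset(proper.epsilon[e]), span))
            continue
        path = (u,) + chain + (v,)
        tuple_sets = {frozenset(proper.epsilon[(a, b)])
                      for a, b in zip(path, path[1:])}
        if len(tuple_sets) != 1:  # pragma: no cover - copies by construction
            raise GmsaError(f"non-uniform multi-edge sets along chain of {e}")
        out.append(DrawableEdge(u, v, next(iter(tuple_sets)), span,
                                route_track=tracks.y[chain[0]]))
    return out


def bundle_edges(d: DrawableEdge, cfg: RoutingConfig = RoutingConfig()) -> list[EdgeBundle]:
    """Partition a drawable edge's tuples by direction: 1 or 2 bundles.

    The line width is proportional to the member count, capped so very
    thick bundles stay readable; forward comes first so a forward /
    backward pair is placed adjacent, forward nearer the vertex middle.
    """
    out = []
    for direction in (FORWARD, "backward"):
        members = tuple(sorted(s for dd, s in d.tuples if dd == direction))
        if members:
            width = min(len(members) * cfg.member_px, cfg.max_bundle_px)
            out.append(EdgeBundle(d.u, d.v, direction, members, width,
                                  d.route_track, d.span))
    if not out:  # pragma: no cover - drawables always carry tuples
        raise GmsaError(f"drawable edge {(d.u, d.v)} has no members")
    return out


# ---------------------------------------------------------------------------
# Connection points, slots, space parameters
# ---------------------------------------------------------------------------

def _zone(own_track: int, target_track: int) -> str:
    if target_track < own_track:
        return UP
    if target_track > own_track:
        return DOWN
    return STRAIGHT


def _target_track(b: EdgeBundle, end: str, tracks: TrackAssignment) -> int:
    """Track the first/last segment heads for, seen from endpoint ``end``."""
    if b.is_long and b.route_track is not None:
        return b.route_track
    return tracks.y[b.v] if end == "u" else tracks.y[b.u]


def _ykey(track: int, zone: str, offset: float) -> float:
    """Deterministic proxy for the absolute y of a connection point."""
    base = track * 10_000.0
    if zone == UP:
        return base - 2_000.0 + offset
    if zone == DOWN:
        return base + 2_000.0 - offset
    return base + offset


class _Router:
    def __init__(self, proper: ProperDAG, tracks: TrackAssignment,
                 cfg: RoutingConfig):
        self.proper = proper
        self.tracks = tracks
        self.cfg = cfg

    # -- step 2: relative edge-vertex connection coordinates -------------
    def place_connections(self, bundles: list[EdgeBundle]
                          ) -> dict[tuple[tuple[str, str, str], str], Connection]:
        cfg = self.cfg
        by_vertex_side: dict[tuple[str, str], list[tuple[EdgeBundle, str]]] = {}
        for b in bundles:
            by_vertex_side.setdefault((b.u, "R"), []).append((b, "u"))
            by_vertex_side.setdefault((b.v, "L"), []).append((b, "v"))

        conns: dict[tuple[tuple[str, str, str], str], Connection] = {}
        for (vertex, side), incident in sorted(by_vertex_side.items()):
            own = self.tracks.y[vertex]
            zones: dict[str, list[tuple[EdgeBundle, str]]] = {z: [] for z in _ZONES}
            for b, end in incident:
                zones[_zone(own, _target_track(b, end, self.tracks))].append((b, end))

            for zone, group in zones.items():
                # stack order: outermost target first, forward before
                # backward within one drawable edge (nearer the middle)
                def sortkey(item: tuple[EdgeBundle, str]):
                    b, end = item
                    tgt = _target_track(b, end, self.tracks)
                    other_layer = b.span[1] if end == "u" else b.span[0]
                    return (tgt, other_layer, b.direction != FORWARD, b.members)

                group.sort(key=sortkey)
                if zone == DOWN:
                    group.reverse()  # measured from the bottom border
                run = cfg.bs_border
                if zone == STRAIGHT:
                    total = (sum(b.width for b, _ in group)
                             + cfg.fs * max(0, len(group) - 1))
                    run = -total / 2.0
                for b, end in group:
                    center = run + b.width / 2.0
                    conns[(b.key, end)] = Connection(vertex, side, zone,
                                                     center, b.width)
                    run += b.width + cfg.fs
        return conns

    # -- step 3: horizontal layering of the vertical lines ----------------
    def assign_slots(self, bundles: list[EdgeBundle],
                     conns: dict[tuple[tuple[str, str, str], str], Connection]
                     ) -> dict[int, list[Slot]]:
        cfg = self.cfg
        wanted: dict[int, list[tuple[float, EdgeBundle, str]]] = {}

        def conn_ykey(b: EdgeBundle, end: str) -> float:
            c = conns[(b.key, end)]
            return _ykey(self.tracks.y[c.vertex], c.zone, c.offset)

        for b in bundles:
            yu, yv = conn_ykey(b, "u"), conn_ykey(b, "v")
            if not b.is_long:
                if yu != yv:
                    mid = (yu + yv) / 2.0
                    wanted.setdefault(b.span[0], []).append((mid, b, "jog"))
                continue
            run_y = b.route_track * 10_000.0  # run sits at its track's midline
            if yu != run_y:
                wanted.setdefault(b.span[0], []).append(((yu + run_y) / 2.0, b, "start"))
            if yv != run_y:
                wanted.setdefault(b.span[1] - 1, []).append(((yv + run_y) / 2.0, b, "end"))

        slots: dict[int, list[Slot]] = {}
        for gap in sorted(wanted):
            entries = sorted(wanted[gap], key=lambda t: (t[0], t[1].key, t[2]))
            run = cfg.bs_border
            placed = []
            for _, b, kind in entries:
                placed.append(Slot(gap, b.key, kind, b.width,
                                   run + b.width / 2.0))
                run += b.width + cfg.fs
            slots[gap] = placed
        return slots

    # -- step 4: space parameters -----------------------------------------
    def space_params(self, bundles: list[EdgeBundle],
                     conns: dict[tuple[tuple[str, str, str], str], Connection],
                     slots: dict[int, list[Slot]]) -> SpaceParams:
        cfg = self.cfg
        height = cfg.min_vertex_height
        by_vertex_side: dict[tuple[str, str], dict[str, list[float]]] = {}
        for (key, end), c in conns.items():
            z = by_vertex_side.setdefault((c.vertex, c.side), {z: [] for z in _ZONES})
            z[c.zone].append(c.width)

        def zone_height(widths: list[float]) -> float:
            if not widths:
                return 0.0
            return sum(widths) + cfg.fs * (len(widths) - 1)

        for zones in by_vertex_side.values():
            asym = max(zone_height(zones[UP]), zone_height(zones[DOWN]))
            h = 2.0 * (cfg.bs_border + asym + (cfg.fs if asym else 0.0)) \
                + zone_height(zones[STRAIGHT])
            height = max(height, h)

        gap_space = cfg.min_inter_layer_space
        for placed in slots.values():
            w = (2.0 * cfg.bs_border + sum(s.width for s in placed)
                 + cfg.fs * (len(placed) - 1))
            gap_space = max(gap_space, w)
        return SpaceParams(height, gap_space, cfg.fs, cfg.bs_border)


def route_edges(proper: ProperDAG, tracks: TrackAssignment,
                cfg: RoutingConfig = RoutingConfig()) -> RoutingResult:
    """Run the full routing step: collapse, bundle, place, slot, measure."""
    router = _Router(proper, tracks, cfg)
    drawables = collapse_dummies(proper, tracks)
    bundles = [b for d in drawables for b in bundle_edges(d, cfg)]
    conns = router.place_connections(bundles)
    slots = router.assign_slots(bundles, conns)
    space = router.space_params(bundles, conns, slots)
    return RoutingResult(drawables, bundles, conns, slots, space, tracks)
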