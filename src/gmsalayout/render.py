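"""Final drawing: grid geometry and SVG output.

Vertices are rectangles on a grid: the layer gives the column, the
block-set track the row.  All vertices share one height (at least the
*needed vertex height* from the routing step); all columns share the
width of the widest vertex, narrower vertices centered; the gap between
columns is at least the *needed inter layer space*.  A vertex's width
encodes the nucleotide length of its block(s) on a clamped log scale so
multi-kilobase blocks stay on screen next to short ones.

Single alignment blocks are filled blue, merged blocks orange.  Every
original sequence adjacency is drawn as its own polyline in the
sequence's color (members of a bundle are offset by one line width so
each contig stays traceable).  Directional glyphs inside a vertex show
each contig's reading direction (right = forward, left = reverse
complement, both = mixed strands after merging); triangular flags mark
each contig's first (right-pointing) and last (left-pointing) vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

from .layering import ProperDAG
from .model_io import GMSAGraph, GmsaError
from .routing import Connection, EdgeRoute, RoutingResult

__all__ = ["RenderConfig", "Geometry", "final_geometry", "render_svg"]


@dataclass(frozen=True)
class RenderConfig:
    """Pixel-level appearance knobs."""

    min_vertex_width: float = 36.0
    max_vertex_width: float = 110.0
    vertex_gap_y: float = 18.0
    margin: float = 24.0
    background: str = "white"
    vertex_fill: str = "#6f9fd8"        # single alignment block
    merged_fill: str = "#f0a13a"        # merged alignment block
    vertex_stroke: str = "#2b2b2b"
    label_vertices: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_vertex_width <= self.max_vertex_width:
            raise GmsaError("vertex widths must satisfy 0 < min <= max")


def vertex_width(length_nt: int, longest_nt: int, cfg: RenderConfig) -> float:
    """Clamped log-scale width: monotone non-decreasing in length."""
    if longest_nt <= 1 or length_nt <= 1:
        return cfg.min_vertex_width
    frac = math.log10(length_nt) / math.log10(longest_nt)
    w = cfg.min_vertex_width + (cfg.max_vertex_width - cfg.min_vertex_width) * frac
    return min(max(w, cfg.min_vertex_width), cfg.max_vertex_width)


@dataclass
class Geometry:
    """Absolute pixel coordinates of the whole drawing."""

    boxes: dict[str, tuple[float, float, float, float]]  # vertex -> x, y, w, h
    routes: list[EdgeRoute]
    row_y: dict[int, float]     # track -> top y of its row
    col_x: dict[int, float]     # layer -> left x of its column
    col_width: float
    vertex_height: float
    size: tuple[float, float]
    bends_histogram: dict[int, int] = field(default_factory=dict)

    def connection_xy(self, c: Connection) -> tuple[float, float]:
        x, y, w, h = self.boxes[c.vertex]
        cx = x if c.side == "L" else x + w
        if c.zone == "up":
            return cx, y + c.offset
        if c.zone == "down":
            return cx, y + h - c.offset
        return cx, y + h / 2.0 + c.offset


def final_geometry(g: GMSAGraph, proper: ProperDAG, routing: RoutingResult,
                   cfg: RenderConfig = RenderConfig()) -> Geometry:
    """Place vertices on the grid and turn the relative edge coordinates
    into absolute orthogonal polylines."""
    space = routing.space
    tracks = routing.tracks
    height = space.needed_vertex_height

    longest = max(b.length_nt for b in g.blocks.values())
    widths = {v: vertex_width(g.blocks[v].length_nt, longest, cfg)
              for v in proper.real_vertices}
    col_width = max(widths.values())
    gap_width = space.needed_inter_layer_space

    used_tracks = sorted(set(tracks.track.values()) | {0})
    row_y = {t: cfg.margin + i * (height + cfg.vertex_gap_y)
             for i, t in enumerate(used_tracks)}
    n_layers = proper.n_layers
    col_x = {l: cfg.margin + l * (col_width + gap_width) for l in range(n_layers)}

    boxes = {}
    for v in sorted(proper.real_vertices):
        l, t = proper.layer[v], tracks.y[v]
        w = widths[v]
        x = col_x[l] + (col_width - w) / 2.0
        boxes[v] = (x, row_y[t], w, height)

    geo = Geometry(
        boxes=boxes, routes=[], row_y=row_y, col_x=col_x,
        col_width=col_width, vertex_height=height,
        size=(2 * cfg.margin + n_layers * col_width + (n_layers - 1) * gap_width,
              2 * cfg.margin + len(used_tracks) * height
              + (len(used_tracks) - 1) * cfg.vertex_gap_y),
    )

    def slot_x(slot) -> float:
        return col_x[slot.gap] + col_width + slot.offset

    def run_midline(track: int) -> float:
        return row_y[track] + height / 2.0

    for b in routing.bundles:
        pu = geo.connection_xy(routing.connections[(b.key, "u")])
        pv = geo.connection_xy(routing.connections[(b.key, "v")])
        pts: list[tuple[float, float]] = [pu]
        if not b.is_long:
            jog = routing.slot_for(b.key, "jog")
            if jog is not None:
                sx = slot_x(jog)
                pts += [(sx, pu[1]), (sx, pv[1])]
        else:
            ry = run_midline(b.route_track)
            start = routing.slot_for(b.key, "start")
            end = routing.slot_for(b.key, "end")
            if start is not None:
                sx = slot_x(start)
                pts += [(sx, pu[1]), (sx, ry)]
            if end is not None:
                ex = slot_x(end)
                pts += [(ex, ry), (ex, pv[1])]
        pts.append(pv)
        geo.routes.append(EdgeRoute(bundle=b, polyline=pts))

    for r in geo.routes:
        geo.bends_histogram[r.bends] = geo.bends_histogram.get(r.bends, 0) + 1
    return geo


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _poly_points(pts: list[tuple[float, float]]) -> str:
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)


def _shift(pts: list[tuple[float, float]], d: float) -> list[tuple[float, float]]:
    # uniform (d, d) translation keeps an orthogonal polyline orthogonal
    return [(x + d, y + d) for x, y in pts]


def _arrow(cx: float, cy: float, size: float, direction: str) -> str:
    s = size
    if direction == "right":
        pts = [(cx - s, cy - s / 2), (cx + s, cy), (cx - s, cy + s / 2)]
    elif direction == "left":
        pts = [(cx + s, cy - s / 2), (cx - s, cy), (cx + s, cy + s / 2)]
    else:  # both: double-headed
        pts = [(cx - s, cy), (cx - s / 4, cy - s / 2), (cx - s / 4, cy - s / 6),
               (cx + s / 4, cy - s / 6), (cx + s / 4, cy - s / 2), (cx + s, cy),
               (cx + s / 4, cy + s / 2), (cx + s / 4, cy + s / 6),
               (cx - s / 4, cy + s / 6), (cx - s / 4, cy + s / 2)]
    return _poly_points(pts)


def render_svg(geometry: Geometry, g: GMSAGraph,
               cfg: RenderConfig = RenderConfig()) -> str:
    """Produce a standalone SVG document (deterministic byte-for-byte
    for a fixed graph, layout and configuration)."""
    colors = {s.name: s.color or "gray" for s in g.sequences}
    for s in g.sequences:
        if not colors[s.name]:
            raise GmsaError(f"sequence {s.name} has no display color")

    W, H = geometry.size
    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _fmt(W), "height": _fmt(H),
        "viewBox": f"0 0 {_fmt(W)} {_fmt(H)}",
    })
    ET.SubElement(svg, "rect", {
        "x": "0", "y": "0", "width": _fmt(W), "height": _fmt(H),
        "fill": cfg.background, "class": "background"})

    # --- edges (each bundled member drawn individually) -----------------
    edges_grp = ET.SubElement(svg, "g", {"class": "edges", "fill": "none"})
    member_px = 1.0
    for r in geometry.routes:
        b = r.bundle
        k = len(b.members)
        for q, seq_name in enumerate(b.members):
            d = (q - (k - 1) / 2.0) * member_px
            ET.SubElement(edges_grp, "polyline", {
                "points": _poly_points(_shift(r.polyline, d)),
                "stroke": colors[seq_name],
                "stroke-width": _fmt(member_px),
                "class": "seq-edge",
                "data-seq": seq_name,
                "data-direction": b.direction,
            })

    # --- vertices --------------------------------------------------------
    verts_grp = ET.SubElement(svg, "g", {"class": "vertices"})
    for v in sorted(geometry.boxes):
        x, y, w, h = geometry.boxes[v]
        block = g.blocks[v]
        rect = ET.SubElement(verts_grp, "rect", {
            "x": _fmt(x), "y": _fmt(y), "width": _fmt(w), "height": _fmt(h),
            "fill": cfg.merged_fill if block.is_merged else cfg.vertex_fill,
            "stroke": cfg.vertex_stroke, "stroke-width": "1",
            "class": "vertex merged" if block.is_merged else "vertex",
            "data-block": v,
        })
        title = ET.SubElement(rect, "title")
        title.text = f"{v} ({block.length_nt} nt" + \
            (f", merged from {len(block.merged_from)} blocks)" if block.is_merged else ")")

        # directional glyphs: one per traversing contig with aligned rows
        glyph_rows = []
        for s in g.sequences:
            if v not in s.vertices:
                continue
            strands = block.strands_of(s.name)
            if not strands:
                continue  # artificial orders carry no aligned interval
            if strands == {1}:
                direction = "right"
            elif strands == {-1}:
                direction = "left"
            else:
                direction = "both"
            glyph_rows.append((s.name, direction))
        size = min(4.0, w / 4.0)
        if glyph_rows:
            step = h / (len(glyph_rows) + 1)
            for i, (seq_name, direction) in enumerate(glyph_rows, start=1):
                ET.SubElement(verts_grp, "polygon", {
                    "points": _arrow(x + w / 2.0, y + i * step, size, direction),
                    "fill": colors[seq_name],
                    "class": f"glyph dir-{direction}",
                    "data-seq": seq_name,
                })

    # --- start / end flags ------------------------------------------------
    flags_grp = ET.SubElement(svg, "g", {"class": "flags"})
    fh = 7.0
    for s in g.sequences:
        for which, v in (("start", s.vertices[0]), ("end", s.vertices[-1])):
            if v not in geometry.boxes:
                continue
            x, y, w, h = geometry.boxes[v]
            if which == "start":  # right-pointing flag at the top-left corner
                pts = [(x, y - fh), (x + fh, y - fh / 2.0), (x, y)]
            else:                 # left-pointing flag at the top-right corner
                pts = [(x + w, y - fh), (x + w - fh, y - fh / 2.0), (x + w, y)]
            ET.SubElement(flags_grp, "polygon", {
                "points": _poly_points(pts),
                "fill": colors[s.name], "stroke": cfg.vertex_stroke,
                "stroke-width": "0.5",
                "class": f"flag flag-{which}", "data-seq": s.name,
            })

    return ET.tostring(svg, encoding="unicode") + "\n"
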