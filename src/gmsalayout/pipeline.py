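"""End-to-end layout pipeline.

Chains every stage — normalization, cycle removal, layering, ordering,
track assignment, routing, rendering — and collects a machine-readable
report of the structural quantities a user cares about (vertex and
dummy counts, reversed bypaths, crossings before/after sifting, tracks,
bend histogram).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from . import preprocess
from .coordinates import TrackAssignment, assign_tracks
from .cycle_removal import LayoutDAG, build_dag
from .layering import Layering, ProperDAG, assign_layers, make_proper
from .model_io import GMSAGraph, require_valid
from .ordering import (BlockSet, build_block_sets, count_crossings,
                       count_type2_crossings, derive_vertex_order, global_sift)
from .render import Geometry, RenderConfig, final_geometry, render_svg
from .routing import RoutingConfig, RoutingResult, route_edges

__all__ = ["PipelineConfig", "LayoutResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline in one place."""

    merge: bool = True
    range_nt: tuple[int, int] | None = None
    rounds: int = 10
    strict_otherwise_reverse: bool = False
    routing: RoutingConfig = field(default_factory=RoutingConfig)
    render: RenderConfig = field(default_factory=RenderConfig)


@dataclass
class LayoutResult:
    """Every intermediate product of one layout run plus the report."""

    graph: GMSAGraph
    dag: LayoutDAG
    layering: Layering
    proper: ProperDAG
    block_sets: list[BlockSet]
    order: list[BlockSet]
    crossing_history: list[int]
    tracks: TrackAssignment
    routing: RoutingResult
    geometry: Geometry
    svg: str
    report: dict[str, Any]


def run_pipeline(g: GMSAGraph, config: PipelineConfig = PipelineConfig()) -> LayoutResult:
    """Lay out a gMSA graph and render it to SVG."""
    require_valid(g, "pipeline input")
    if config.range_nt is not None:
        g = preprocess.extract_range(g, *config.range_nt)
    if config.merge:
        g = preprocess.merge_colinear_blocks(g)
    g = preprocess.trim_to_guide(g)

    dag = build_dag(g, strict_otherwise_reverse=config.strict_otherwise_reverse)
    layering = assign_layers(dag)
    proper = make_proper(dag, layering)
    block_sets = build_block_sets(proper, dag)
    order, history = global_sift(block_sets, proper, rounds=config.rounds)
    index_gs = next(i for i, bs in enumerate(order) if bs.origin == dag.guide_name)
    tracks = assign_tracks(order, index_gs)
    routing = route_edges(proper, tracks, config.routing)
    geometry = final_geometry(g, proper, routing, config.render)
    svg = render_svg(geometry, g, config.render)

    final_order = derive_vertex_order(order, proper.n_layers)
    report = {
        "n_sequences": len(g.sequences),
        "n_vertices": len(g.blocks),
        "n_merged_vertices": sum(1 for b in g.blocks.values() if b.is_merged),
        "n_multi_edges": g.n_multi_edges(),
        "n_dag_edges": len(dag.edges),
        "n_bypaths": len(dag.records),
        "n_reversed_bypaths": sum(1 for r in dag.records if r.reversed),
        "n_layers": proper.n_layers,
        "n_dummy_vertices": len(proper.dummy_vertices),
        "n_block_sets": len(block_sets),
        "crossings_before": history[0],
        "crossings_after": history[-1],
        "sifting_rounds_run": len(history) - 1,
        "type2_crossings": count_type2_crossings(final_order, proper),
        "n_tracks": tracks.n_tracks,
        "tracks_above": -min(0, tracks.min_track),
        "tracks_below": max(0, tracks.max_track),
        "n_bundles": len(routing.bundles),
        "bends_histogram": dict(sorted(geometry.bends_histogram.items())),
        "needed_vertex_height": routing.space.needed_vertex_height,
        "needed_inter_layer_space": routing.space.needed_inter_layer_space,
        "svg_size": geometry.size,
    }
    return LayoutResult(g, dag, layering, proper, block_sets, order, history,
                        tracks, routing, geometry, svg, report)
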