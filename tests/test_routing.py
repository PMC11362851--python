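"""Dummy collapse, bundling, connection zones, slots, space parameters."""

from __future__ import annotations

import dataclasses

import pytest

import gmsalayout as gl
from gmsalayout.routing import DOWN, STRAIGHT, UP, RoutingConfig

from conftest import make_graph


def layout_upto_routing(g, cfg=RoutingConfig()):
    dag = gl.build_dag(g)
    proper = gl.make_proper(dag, gl.assign_layers(dag))
    sets = gl.build_block_sets(proper, dag)
    order, _ = gl.global_sift(sets, proper)
    index_gs = next(i for i, bs in enumerate(order) if bs.origin == dag.guide_name)
    tracks = gl.assign_tracks(order, index_gs)
    return dag, proper, tracks, gl.route_edges(proper, tracks, cfg)


class TestCollapseDummies:
    def test_tight_edge_passthrough(self, guide_only):
        dag, proper, tracks, routing = layout_upto_routing(guide_only)
        assert all(d.route_track is None for d in routing.drawables)
        assert len(routing.drawables) == 4

    def test_long_edge_collapses_to_one_drawable_with_chain_track(self):
        g = make_graph(["a", "b", "c", "d"], ["a", "d"])
        dag, proper, tracks, routing = layout_upto_routing(g)
        long = next(d for d in routing.drawables if (d.u, d.v) == ("a", "d"))
        assert long.is_long and long.span == (0, 3)
        chain = proper.chain_of[("a", "d")]
        assert long.route_track == tracks.y[chain[0]] != 0

    def test_drawable_count_equals_original_edge_count(self, small_synthetic):
        dag, proper, tracks, routing = layout_upto_routing(small_synthetic)
        assert len(routing.drawables) == len(dag.edges)


class TestBundling:
    def test_same_direction_tuples_bundle(self):
        d = gl.DrawableEdge("a", "b", frozenset({("forward", "S1"),
                                                 ("forward", "S2")}), (0, 1))
        bundles = gl.bundle_edges(d)
        assert len(bundles) == 1
        assert bundles[0].members == ("S1", "S2")
        assert bundles[0].width == 2.0

    def test_mixed_directions_give_two_adjacent_bundles(self):
        d = gl.DrawableEdge("a", "b", frozenset({("forward", "S1"),
                                                 ("backward", "S2")}), (0, 1))
        bundles = gl.bundle_edges(d)
        assert [b.direction for b in bundles] == ["forward", "backward"]
        assert sum(len(b.members) for b in bundles) == 2

    def test_width_capped(self):
        cfg = RoutingConfig(member_px=1.0, max_bundle_px=6.0)
        d = gl.DrawableEdge("a", "b",
                            frozenset(("forward", f"S{k}") for k in range(10)),
                            (0, 1))
        assert gl.bundle_edges(d, cfg)[0].width == 6.0

    def test_at_most_two_bundles_per_drawable(self, small_synthetic):
        dag, proper, tracks, routing = layout_upto_routing(small_synthetic)
        per_edge = {}
        for b in routing.bundles:
            per_edge.setdefault((b.u, b.v), []).append(b)
        for bundles in per_edge.values():
            assert 1 <= len(bundles) <= 2
            assert len({b.direction for b in bundles}) == len(bundles)


class TestConnections:
    def test_single_straight_bundle_centered(self, guide_only):
        dag, proper, tracks, routing = layout_upto_routing(guide_only)
        for (key, end), c in routing.connections.items():
            assert c.zone == STRAIGHT and c.offset == 0.0

    def test_zones_follow_vertical_orientation(self):
        g = make_graph(["a", "b", "c"], ["a", "x", "c"], ["a", "y", "c"])
        dag, proper, tracks, routing = layout_upto_routing(g)
        for b in routing.bundles:
            c = routing.connections[(b.key, "u")]
            tu = tracks.y[b.u]
            tv = b.route_track if b.is_long else tracks.y[b.v]
            expect = UP if tv < tu else DOWN if tv > tu else STRAIGHT
            assert c.zone == expect
            assert c.side == "R"
            assert routing.connections[(b.key, "v")].side == "L"

    def test_same_zone_bundles_separated_by_free_space(self):
        cfg = RoutingConfig(fs=4.0, bs_border=6.0)
        g = make_graph(["a", "b", "c", "d", "e"],
                       ["a", "x", "c"], ["a", "y", "e"])
        dag, proper, tracks, routing = layout_upto_routing(g, cfg)
        by_side: dict = {}
        for (key, end), c in routing.connections.items():
            by_side.setdefault((c.vertex, c.side, c.zone), []).append(c)
        for conns in by_side.values():
            offs = sorted((c.offset, c.width) for c in conns)
            for (o1, w1), (o2, w2) in zip(offs, offs[1:]):
                assert o2 - o1 >= (w1 + w2) / 2 + cfg.fs - 1e-9

    def test_opposite_vertices_down_bundles_get_distinct_slots(self):
        # u and w sit on the same track with down-edges into the same
        # gap: their vertical segments may not share an x slot
        g = make_graph(["a", "b", "c"], ["a", "x", "b", "y", "c"])
        dag, proper, tracks, routing = layout_upto_routing(g)
        for slots in routing.slots.values():
            offsets = [s.offset for s in slots]
            assert len(offsets) == len(set(offsets))


class TestSlots:
    def test_all_straight_gap_has_no_slots(self, guide_only):
        dag, proper, tracks, routing = layout_upto_routing(guide_only)
        assert routing.slots == {}

    def test_slots_unique_and_separated(self):
        cfg = RoutingConfig(fs=4.0)
        for seed in range(10):
            g = gl.generate_synthetic(gl.SyntheticParams(
                n_guide_vertices=12, n_comparative=5, p_insertion=0.35,
                p_deletion=0.3, p_inversion=0.5, seed=seed))
            dag, proper, tracks, routing = layout_upto_routing(g, cfg)
            for slots in routing.slots.values():
                xs = sorted((s.offset, s.width) for s in slots)
                for (o1, w1), (o2, w2) in zip(xs, xs[1:]):
                    assert o2 - o1 >= (w1 + w2) / 2 + cfg.fs - 1e-9

    def test_straight_bundles_need_no_slot(self, small_synthetic):
        dag, proper, tracks, routing = layout_upto_routing(small_synthetic)
        slotted = {s.bundle_key for slots in routing.slots.values() for s in slots}
        for b in routing.bundles:
            cu = routing.connections[(b.key, "u")]
            cv = routing.connections[(b.key, "v")]
            if (not b.is_long and cu.zone == STRAIGHT == cv.zone
                    and cu.offset == cv.offset
                    and tracks.y[b.u] == tracks.y[b.v]):
                assert b.key not in slotted


class TestSpaceParams:
    def test_guide_only_minimal(self, guide_only):
        cfg = RoutingConfig()
        dag, proper, tracks, routing = layout_upto_routing(guide_only, cfg)
        assert routing.space.needed_vertex_height == cfg.min_vertex_height
        assert routing.space.needed_inter_layer_space == cfg.min_inter_layer_space

    def test_vertex_height_grows_with_stacked_bundles(self):
        base = make_graph(["a", "b", "c", "d", "e", "f", "g"],
                          ["a", "x1", "g"])
        tall = make_graph(["a", "b", "c", "d", "e", "f", "g"],
                          ["a", "x1", "g"], ["a", "x2", "g"], ["a", "x3", "g"],
                          ["a", "x4", "g"], ["a", "x5", "g"])
        h1 = layout_upto_routing(base)[3].space.needed_vertex_height
        h2 = layout_upto_routing(tall)[3].space.needed_vertex_height
        assert h2 > h1

    def test_doubling_fs_widens_gaps_with_slots(self):
        g = make_graph(["a", "b", "c", "d"], ["a", "d"], ["a", "c"])
        small = layout_upto_routing(
            g, RoutingConfig(fs=4.0, min_inter_layer_space=1.0))[3]
        big = layout_upto_routing(
            g, RoutingConfig(fs=8.0, min_inter_layer_space=1.0))[3]
        assert any(small.slots.values())
        assert big.space.needed_inter_layer_space > \
            small.space.needed_inter_layer_space

    def test_config_validation(self):
        with pytest.raises(gl.GmsaError):
            RoutingConfig(fs=0)
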