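"""Domain types, JSON/MAF ingest, validation, synthetic generator."""

from __future__ import annotations

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gmsalayout as gl
from gmsalayout.model_io import export_tsv

from conftest import make_graph


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(gl.GmsaError):
            gl.SequenceInterval("G", "c", 10, 5)
        with pytest.raises(gl.GmsaError):
            gl.SequenceInterval("G", "c", 1, 5, sigma=0)
        assert gl.SequenceInterval("G", "c", 3, 7).length == 5

    def test_block_defaults(self):
        b = gl.AlignmentBlock(id="b", rows=(gl.SequenceInterval("G", "c", 1, 40),))
        assert b.merged_from == ("b",) and not b.is_merged and b.length_nt == 40
        with pytest.raises(gl.GmsaError):
            gl.AlignmentBlock(id="e", rows=())

    def test_strands_of_reports_mixed_directions(self):
        rows = (gl.SequenceInterval("G", "c", 1, 5, 1),
                gl.SequenceInterval("G", "c", 10, 20, -1))
        b = gl.AlignmentBlock(id="m", rows=rows, merged_from=("x", "y"))
        assert b.strands_of("G:c") == {1, -1}


class TestJsonDialect:
    def test_identity_round_trip(self, guide_only):
        text = gl.dumps_gmsa(guide_only)
        g2 = gl.loads_gmsa(text)
        assert len(g2.sequences) == 1 and len(g2.blocks) == 5
        assert g2.guide.vertices == guide_only.guide.vertices
        # canonical serialization is a fixpoint (byte-identical)
        assert gl.dumps_gmsa(g2) == text

    def test_round_trip_preserves_rows_and_merges(self, small_synthetic):
        g2 = gl.loads_gmsa(gl.dumps_gmsa(small_synthetic))
        assert gl.dumps_gmsa(g2) == gl.dumps_gmsa(small_synthetic)
        assert g2.n_multi_edges() == small_synthetic.n_multi_edges()

    def test_malformed_json_names_location(self):
        with pytest.raises(gl.GmsaError, match="line"):
            gl.loads_gmsa("{\n  broken")

    def test_unanchored_comparative_rejected(self):
        g = make_graph(["a", "b", "c"], ["a", "x"])  # ends off-guide
        text = gl.dumps_gmsa(g)
        with pytest.raises(gl.GmsaError, match="anchor"):
            gl.loads_gmsa(text)

    def test_tsv_export_flattens_rows(self, diamond):
        tsv = export_tsv(diamond)
        lines = tsv.strip().split("\n")
        n_rows = sum(len(b.rows) for b in diamond.blocks.values())
        assert len(lines) == n_rows + 1
        assert lines[0].startswith("block\t")


class TestValidate:
    def test_valid_graph_has_no_violations(self, small_synthetic):
        assert gl.validate(small_synthetic) == []

    def test_revisited_vertex_is_path_violation(self):
        g = make_graph(["a", "b", "c"])
        g.sequences[0] = gl.VertexSequence("G0", "c0", ("a", "b", "a"), "red")
        kinds = {v.kind for v in gl.validate(g)}
        assert "not-a-path" in kinds

    def test_short_sequence_and_unknown_block(self):
        g = make_graph(["a", "b", "c"])
        g.sequences.append(gl.VertexSequence("G1", "c1", ("a",), "green"))
        kinds = {v.kind for v in gl.validate(g)}
        assert "short-sequence" in kinds
        g.sequences[1] = gl.VertexSequence("G1", "c1", ("a", "zz"), "green")
        kinds = {v.kind for v in gl.validate(g)}
        assert "unknown-block" in kinds and "anchoring" in kinds

    def test_single_hit_rule(self):
        rows = (gl.SequenceInterval("G0", "c0", 1, 5),
                gl.SequenceInterval("G0", "c0", 50, 60))
        g = make_graph(["a", "b"])
        g.blocks["a"] = gl.AlignmentBlock(id="a", rows=rows)
        kinds = {v.kind for v in gl.validate(g)}
        assert "single-hit" in kinds


MAF_FIXTURE = """##maf version=1
a score=10.0
s G1.c1  0 20 + 200 N
s G2.c2  0 20 + 300 N

a score=10.0
s G1.c1 20 30 + 200 N
s G2.c2 20 30 + 300 N
s G3.c3 250 30 - 300 N

a score=10.0
s G1.c1 50 40 + 200 N
s G3.c3 100 40 + 300 N

a score=10.0
s G2.c2 50 25 + 300 N
s G1.c1 90 25 + 200 N
"""


class TestMafIngest:
    def test_vertex_sequences_match_coordinate_sort(self, tmp_path):
        # oracle: independently sort each contig's (start, block) pairs
        path = tmp_path / "toy.maf"
        path.write_text(MAF_FIXTURE)
        g = gl.load_maf(path)
        assert [s.name for s in g.sequences] == ["G1:c1", "G2:c2", "G3:c3"]
        expected = {
            "G1:c1": ("b0", "b1", "b2", "b3"),   # starts 0, 20, 50, 90
            "G2:c2": ("b0", "b1", "b3"),          # starts 0, 20, 50
            "G3:c3": ("b1", "b2"),                # forward starts 20, 100
        }
        for s in g.sequences:
            assert s.vertices == expected[s.name]
        assert gl.validate(g) == []

    def test_reverse_strand_coordinates_converted(self, tmp_path):
        path = tmp_path / "toy.maf"
        path.write_text(MAF_FIXTURE)
        g = gl.load_maf(path)
        row = next(r for r in g.blocks["b1"].rows if r.seq_name == "G3:c3")
        # srcSize 300, strand-relative start 250, size 30 -> forward 20..50
        assert (row.i, row.j, row.sigma) == (21, 50, -1)

    def test_guide_override(self, tmp_path):
        path = tmp_path / "toy.maf"
        path.write_text(MAF_FIXTURE)
        g = gl.load_maf(path, guide="G2:c2", check=False)
        assert g.guide.name == "G2:c2"
        # with this guide, G3:c3 is no longer anchored — validate says so
        assert any(v.kind == "anchoring" for v in gl.validate(g))
        with pytest.raises(gl.GmsaError, match="guide"):
            gl.load_maf(path, guide="G9:c9")


class TestSyntheticGenerator:
    def test_guide_only(self):
        g = gl.generate_synthetic(gl.SyntheticParams(
            n_guide_vertices=5, n_comparative=0, seed=1))
        assert len(g.sequences) == 1 and len(g.guide) == 5
        assert g.n_multi_edges() == 4

    def test_deterministic_per_seed(self):
        p = gl.SyntheticParams(n_guide_vertices=15, n_comparative=4, seed=33)
        assert gl.dumps_gmsa(gl.generate_synthetic(p)) == \
            gl.dumps_gmsa(gl.generate_synthetic(p))

    def test_forced_inversion_yields_reversed_run(self):
        p = gl.SyntheticParams(n_guide_vertices=5, n_comparative=1,
                               p_insertion=0.0, p_deletion=0.0,
                               p_inversion=1.0, seed=11)
        g = gl.generate_synthetic(p)
        comp = g.comparatives[0]
        guide = list(g.guide.vertices)
        assert gl.validate(g) == []
        # some maximal sub-run of the comparative is the guide reversed,
        # with flipped strands on its rows
        rev_rows = [v for v in comp.vertices
                    if -1 in g.blocks[v].strands_of(comp.name)]
        idx = [guide.index(v) for v in comp.vertices]
        assert rev_rows, "inversion with p=1 must flip at least one strand"
        assert any(idx[k] > idx[k + 1] for k in range(len(idx) - 1))

    def test_infeasible_params_rejected(self):
        with pytest.raises(gl.GmsaError):
            gl.SyntheticParams(n_guide_vertices=1)
        with pytest.raises(gl.GmsaError):
            gl.SyntheticParams(p_insertion=1.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           n_guide=st.integers(2, 25), n_comp=st.integers(0, 6),
           p_ins=st.floats(0, 1), p_del=st.floats(0, 1), p_inv=st.floats(0, 1))
    def test_every_generated_graph_validates(self, seed, n_guide, n_comp,
                                             p_ins, p_del, p_inv):
        g = gl.generate_synthetic(gl.SyntheticParams(
            n_guide_vertices=n_guide, n_comparative=n_comp,
            p_insertion=p_ins, p_deletion=p_del, p_inversion=p_inv, seed=seed))
        assert gl.validate(g) == []

    def test_thousand_seeded_draws_validate(self):
        for seed in range(1000):
            g = gl.generate_synthetic(gl.SyntheticParams(
                n_guide_vertices=4 + seed % 12, n_comparative=seed % 4,
                p_insertion=0.3, p_deletion=0.3, p_inversion=0.3, seed=seed))
            assert gl.validate(g) == []
            assert g.n_multi_edges() == sum(len(s) - 1 for s in g.sequences)
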