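# gmsalayout

Layered, guide-anchored drawings of **genome-wide multiple sequence
alignment (gMSA) graphs**.

When whole genomes are aligned, each contig is cut into alignment
blocks, and the blocks induce a total order per contig.  The union of
these per-contig orders is a directed multi-graph — the gMSA graph —
whose structure exposes insertions, deletions, inversions and
rearrangements between genomes at a semi-global scale, including
artificial orders such as a supergenome coordinate system.  This
package lays such graphs out so that one reference contig (the *guide
sequence*, GS) runs linearly left to right on a single horizontal
track, and every *comparative sequence* (CS) is drawn around it, with
contiguous sub-sequences horizontally aligned and edges routed
orthogonally.  It is aimed at bioinformaticians who want to compare
genome orders visually — much like a genome browser, but with the
alignment-block adjacency structure of *all* genomes in one picture.

## The layout pipeline

The layout is an extended Sugiyama (layered) framework with algorithms
tailored to sequence comparison rather than minimum edge reversal:

1. **Cycle removal by bypath insertion.**  The guide sequence is
   inserted first, all edges forward.  Each comparative sequence, in
   its user-given priority order (the *genome order*), is split into
   *bypaths* — sub-paths whose endpoints are already-processed vertices
   — and each bypath is inserted whole, forward or reversed, decided by
   the current reachability between its endpoints (successor map σ,
   predecessor map τ).  A multiple-edge map ε records, per DAG edge,
   the set of `(direction, sequence)` tuples it stands for, so no edge
   ever needs to be un-reversed.  The resulting DAG has exactly one
   source (the guide's first vertex) and one sink (its last).
2. **Longest-path layering**, made *proper* by dummy-vertex chains on
   long edges (ε is copied onto every chain edge).
3. **Crossing reduction by block-set sifting** — a variant of global
   sifting that moves the whole run of blocks induced by one bypath as
   a unit, so bypath runs stay horizontally alignable and crossings
   between two dummy chains (Type 2 conflicts) cannot occur.
4. **Track assignment**: block-sets are stacked onto integer tracks
   above/below the guide (track 0), as close to it as possible without
   re-ordering block-sets that share a layer — the crossing count of
   the sifted order is preserved exactly.
5. **Orthogonal multi-edge routing**: parallel same-direction edges are
   bundled (line width = multiplicity), bundles attach to left/right
   vertex borders in up/straight/down zones, every vertical segment
   gets a unique slot in its inter-layer gap, and the two space
   parameters *needed vertex height* and *needed inter layer space*
   are derived.  Direct (span-1) edges bend at most twice.
6. **SVG rendering**: vertices on a grid (blue = single block, orange =
   merged block, width encodes block length on a clamped log scale),
   one polyline per sequence adjacency in the sequence's color,
   directional glyphs for strand, triangular start/end flags.

Inputs are a native JSON dialect (blocks + vertex sequences) or MAF
files; a seeded synthetic generator produces realistic random gMSA
graphs so everything is testable without external data.

## Worked example

```sh
gmsa synth --guide-len 12 --comparatives 3 --p-inversion 0.6 --seed 11 -o example.json
gmsa layout example.json -o example.svg --report report.json
```

The layout report printed by the second command:

```json
{
 "bends_histogram": {"0": 12, "2": 14, "4": 4},
 "crossings_after": 0,
 "crossings_before": 15,
 "n_block_sets": 12,
 "n_bundles": 30,
 "n_bypaths": 27,
 "n_dag_edges": 29,
 "n_dummy_vertices": 17,
 "n_layers": 15,
 "n_merged_vertices": 3,
 "n_multi_edges": 45,
 "n_reversed_bypaths": 4,
 "n_sequences": 4,
 "n_tracks": 6,
 "n_vertices": 19,
 "needed_inter_layer_space": 26.0,
 "needed_vertex_height": 43.0,
 "sifting_rounds_run": 2,
 "svg_size": [2062.0, 396.0],
 "tracks_above": 3,
 "tracks_below": 2,
 "type2_crossings": 0
}
```

Reading it: the 4 contigs traverse 19 (merged) alignment blocks via 45
adjacencies; cycle removal split the comparative sequences into 27
bypaths and had to reverse 4 of them (inversions relative to the
guide); sifting removed all 15 initial edge crossings in 2 rounds; the
drawing uses 6 horizontal tracks (guide plus 3 above, 2 below), every
direct edge bends at most twice, and no two long-edge chains cross.
`example.svg` is the finished drawing.

Other commands: `gmsa validate in.json` lists violated input
invariants; `gmsa layout in.maf --guide SenAgo:NC_011148 --range
7744:9984` ingests MAF, picks a guide contig and restricts it to a
nucleotide window.  The same pipeline is available as a library:

```python
import gmsalayout as gl
g = gl.generate_synthetic(gl.SyntheticParams(n_guide_vertices=12, seed=11))
result = gl.run_pipeline(g)
print(result.report["crossings_after"])   # e.g. 0
open("out.svg", "w").write(result.svg)
```

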