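# Methods

This note documents the data model, the algorithms, the parameters
that matter, and the design decisions behind `gmsalayout`.

## Data model and assumptions

A gMSA graph is given as an ordered list of *vertex sequences*: per
contig, the total order of the alignment blocks that tile it.  Blocks
carry their aligned rows `(genome, contig, i, j, σ)` with 1-based
inclusive forward-strand coordinates and a reading direction σ ∈ {+1,
−1}; MAF's 0-based, strand-relative, half-open coordinates are
converted on ingest (reverse-strand rows keep forward coordinates and
σ = −1).  The first sequence is the guide (GS); the rest are
comparative sequences (CS) in decreasing priority (genome order —
supplied by the user, e.g. by phylogenetic proximity; the package does
not order them).

Assumptions enforced by validation:

* every sequence is a **path of distinct vertices** of length ≥ 2.
  Real duplications that revisit a block would violate this; such
  inputs are *rejected* with an explicit error rather than silently
  drawn wrong.  (Duplicating the vertex per visit would be a
  representable alternative; it is deliberately not guessed at.)
* **single hits**: in an unmerged block, a contig appears in at most
  one row.  Merged blocks may hold several rows per contig.
* **anchoring**: every comparative sequence starts and ends on a guide
  vertex.  `trim_to_guide` establishes this by cutting to the maximal
  anchored sub-path, dropping (with a warning) sequences that keep
  fewer than two vertices.

## Normalization

`merge_colinear_blocks` collapses a run of blocks into one merged
vertex when the *identical* set of sequences traverses all of them,
consecutively and in the same order.  This is the strongest reading of
"no information is lost": any weaker predicate (e.g. ignoring
sequences that touch only part of the run) would hide an entry or exit
point of some contig.  Runs are shortened from the right rather than
collapsing any traversing sequence below the 2-vertex minimum, and the
operation iterates to a fixpoint (it is idempotent, and expanding
`merged_from` recovers the original per-sequence orders exactly).
`extract_range` keeps the guide blocks whose guide-row interval
overlaps the window (inclusive on both ends) and then re-anchors the
comparatives; merging runs **after** range extraction in the pipeline,
so a window boundary can never split a merged vertex.

## Cycle removal

Processing order: guide first (all edges forward), then each
comparative in genome order, decomposed into bypaths against the
processed-vertex set and inserted left to right.  For a bypath
(v0, …, vn):

* vn ∈ σ(v0) → insert forward;
* v0 ∈ σ(vn) → insert reversed (forward would close a cycle);
* endpoints unrelated → **forward** by default.  Reversal is only
  *required* in the second case; keeping the original reading
  direction in the unrelated case preserves left-to-right readability
  and is equally cycle-safe (neither endpoint reaches the other, and
  inner vertices are new, so either orientation embeds).  The
  configurable `strict_otherwise_reverse=True` reverses instead, for
  the stricter convention.

An edge is created only if no edge exists between the two vertices in
either direction; the ε map gains exactly one `(direction, sequence)`
tuple per adjacency, with the direction taken relative to the edge
actually kept.  σ and τ are maintained incrementally by the four
update steps (insert `{v} ∪ σv` into `σu`, propagate `σu` to every
`w ∈ τu`; mirrored for τ); the test suite re-derives both maps from
scratch by DFS after **every** insertion and requires equality.

Consequences (tested over hundreds of seeded graphs): the DAG has
exactly one source (guide's first vertex) and one sink (guide's last),
all edges of one bypath share one orientation, and
Σ_e |ε(e)| = Σ_S (|S| − 1).

## Layering and properization

Longest-path layering (`layer(v)` = longest source-to-v path, DP over
a topological order).  The guide occupies strictly increasing layers
starting at 0; it occupies *exactly* layers 0..|GS|−1 whenever no
bypath outspans the guide segment it bridges — an insertion of k > 1
blocks between adjacent guide vertices stretches that edge's span, so
the general guarantee is monotonicity, not contiguity.  Long edges are
replaced by chains of `span − 1` dummy vertices; every chain edge
carries a copy of the long edge's ε set, and the long edge leaves the
map.  Dummy ids are namespaced (`d:<u>><v>:<k>`) for stable output.

## Crossing reduction

Blocks are single real vertices or maximal dummy chains; a *block-set*
is the ordered run of blocks induced by one bypath (inner vertices
plus the chains of the long edges the bypath created), and the guide
forms one block-set of its own (its vertices plus the chains of long
guide edges — these never collide with guide vertices because guide
layers increase monotonically).  A bypath of length 2 normally
contributes nothing; if its single new edge is *long*, the dummy chain
still must be positioned, so such a bypath owns a chain-only
block-set.  Every vertex and dummy is covered exactly once, and a
block-set covers a contiguous layer interval with at most one element
per layer.

Sifting moves whole block-sets: each round tries every block-set at
every position and keeps the best (ties go to the topmost position —
deterministic).  The initial order is construction order (guide
first); the guide block-set sifts like any other, which cannot break
guide linearity because a block-set occupies a single position.
Candidate positions are scored on the crossings involving edges
incident to the moved block-set only (all other pairs are invariant
under the move), which makes a sift step O(positions × incident ×
gap edges) instead of a full recount; the full exact counter
(per-gap inversion counting, verified against an O(E²) pairwise
oracle) is recomputed once per round for the report.  The default is
10 rounds with early stop once a round brings no improvement — the
count is monotone non-increasing, so stopping at a fixpoint loses
nothing.  Because a dummy chain lives inside one block at one
position, two inner edges can never invert between adjacent layers:
Type 2 crossings are structurally impossible, and the suite asserts
zero.  On small instances (≤ 6 block-sets) sifting is compared against
the exhaustive permutation optimum; it may in principle stop in a
local optimum, so the match rate is measured and logged rather than
assumed.

## Track assignment

Two symmetric passes walk the sifted order outward from the guide
(track 0): each block-set is placed one track beyond the farthest
already-placed block-set whose layer span it overlaps (track ±1 if it
overlaps none).  "Intersection" is layer-span overlap: two block-sets
share a layer iff their spans overlap, and the rule keeps every such
pair in sifted order, so the per-layer vertex orders — and hence the
exact crossing count — of the sifted solution are preserved while
disjoint block-sets share tracks.  A pure "smallest free track" greedy
can be one track tighter on nested spans, but can also flip the order
of two block-sets that share a layer, creating crossings the sifting
step just removed; compactness is traded for exact crossing
preservation.  Local optimality still holds in the form: no block-set
can move one track closer to the guide without overlapping a block-set
that the sifted order places nearer.

## Routing

Dummy chains collapse back into one *drawable edge* per original DAG
edge, carrying the chain's ε set and the chain's track as the
horizontal run position (re-reversing edges is unnecessary — ε already
records each member's true direction).  Tuples partition by direction
into at most two *bundles* per drawable edge; a bundle's line width is
`member_px` per member, capped at `max_bundle_px`.

Connection points: bundles attach on the right border of the
lower-layer endpoint and the left border of the higher-layer endpoint
(sides are layer-determined; biological direction is encoded by glyphs
and the ε direction, not by geometry).  The zone — up, straight, down
— follows the vertical orientation of the bundle's first segment
(towards the other endpoint's track, or the route track for long
edges).  Zone stacks are ordered by (target track, far layer, forward
before backward, members) — deterministic, with forward/backward pairs
adjacent — and separated by the free space `FS`; straight bundles are
centered on the vertex midline.

Vertical slots: every bundle whose two ends differ in (track, zone,
offset) needs one vertical segment per jog; long edges need one in
their first and/or last gap (skipped when the connection already sits
on the run's midline).  Within a gap, slots are ordered left-to-right
by the midpoint height of their vertical segment (a documented
heuristic — it tends to shorten segments crossing the gap; any
deterministic order preserves correctness) and separated by `FS`, so
no two vertical segments share an x position — in particular,
down-edges of two opposite vertices always occupy distinct slots.
Direct edges therefore bend 0 or 2 times; collapsed long edges bend at
most 4 times (twice at each end around the horizontal run), and
exactly 2 when the run lies on an endpoint's track — the two-bend
guarantee applies to direct edges.

Space parameters: `needed_vertex_height = 2·(BS + max(up, down) + FS)
+ straight` per vertex side (BS = border space), maximized over
vertices and floored at `min_vertex_height`; `needed_inter_layer_space
= 2·BS + Σ slot widths + FS·(slots − 1)` maximized over gaps and
floored at `min_inter_layer_space`.  Zones cannot overflow: the
drawing grows instead.

Defaults (px): `FS = 4`, `BS = 6`, `member_px = 1`, `max_bundle_px =
6`, `min_vertex_height = 18`, `min_inter_layer_space = 26` — chosen
for readable desk-scale drawings; all configurable.

## Final drawing

Uniform vertex height (= needed vertex height); column width = widest
vertex, narrower vertices centered; rows are used tracks top-to-bottom
separated by `vertex_gap_y` (default 18 px).  Vertex width is
`min + (max − min)·log10(len)/log10(len_max)` clamped to
[`min_vertex_width` = 36, `max_vertex_width` = 110] — monotone in
block length while keeping multi-kilobase blocks on screen.  Members
of a bundle are drawn as individual 1 px polylines, offset by one line
width along both axes (a uniform (d, d) translation keeps an
orthogonal polyline orthogonal), so each contig remains traceable by
color; consequently the SVG contains exactly Σ_S (|S| − 1) edge
polylines.  Single blocks are blue, merged blocks orange; per-contig
directional glyphs point right (σ = +1), left (σ = −1) or both (mixed
strands inside a merged vertex); triangular flags mark each contig's
first (right-pointing) and last (left-pointing) vertex.  Glyph shapes
and sizes are pragmatic approximations.  Output is deterministic byte
for byte for a fixed input and configuration (all iteration orders are
explicit; nothing depends on hash ordering).

## Synthetic generator

The generator emulates bacterial-scale gMSA structure: a guide contig
of `n_guide_vertices` blocks with exponentially distributed lengths
(`mean_block_nt` = 800 nt, the order of magnitude of typical
whole-genome alignment blocks), and comparative contigs derived from
the guide by per-vertex deletion, per-gap insertion of 1..
`max_insert_len` novel blocks, and inversion of one random sub-run
(flipping row strands), then end-trimmed to guide anchors.  Defaults
(`p_insertion = p_deletion = p_inversion = 0.15`, 3 comparatives)
produce moderately rearranged genomes.  It does **not** emulate
duplications (excluded by the path model), translocations between
contigs, alignment noise, or block fragmentation gradients — so
passing tests demonstrate the layout machinery on structurally valid
inputs, not robustness to pathological alignments.  Generation is
deterministic per seed.

## Verification sizes and numerical choices

The test suite and the acceptance script verify the structural
guarantees on seeded batches: 500 graphs with 5–60 guide vertices and
0–8 comparatives for cycle removal and full layouts; 100–200 smaller
graphs (4–14 guide vertices) for the step-by-step σ/τ-versus-DFS
oracle (quadratic in graph size); ≤ 6 block-sets for the exhaustive
permutation comparison (factorial).  These sizes exercise every code
path at desk scale, matching the heuristic's intended interactive use.
All geometric assertions are exact (floating-point arithmetic here is
sums of configured constants; comparisons use 1e-9 slack only where
two independently accumulated sums are compared).  Degenerate inputs —
empty block tables, length-1 sequences, inverted ranges, windows
keeping fewer than two guide vertices — fail fast with named errors.

## Known limitations

* Sifting recounts candidate scores pairwise; complexity is fine for
  hundreds of vertices but not for chromosome-scale graphs with tens
  of thousands of blocks (the quadratic/cubic behavior is inherent to
  the framework; merging co-linear runs is the main mitigation).
* The vertical-position refinement of rare aesthetically unpleasing
  stackings is omitted; `assign_tracks` is the natural hook for such a
  post-pass.
* No spline routing, no interactivity, no annotation tracks; the SVG
  is a static starting point for analysis.
* Genome order is taken as given; choosing it (e.g. phylogenetically)
  strongly shapes the layout and is the user's lever.
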