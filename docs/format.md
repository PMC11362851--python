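# File formats

## Native JSON dialect (`gmsa-graph/1`)

A single JSON object:

```json
{
 "format": "gmsa-graph/1",
 "blocks": [
  {
   "id": "b0",
   "length_nt": 812,
   "merged_from": ["b0"],
   "rows": [
    {"genome": "G0", "contig": "c0", "start": 1, "end": 812, "strand": 1}
   ]
  }
 ],
 "sequences": [
  {"genome": "G0", "contig": "c0", "color": "red", "vertices": ["b0", "b1"]}
 ]
}
```

* `blocks[*].rows` — the aligned sequence intervals of the block, one
  per contig occurrence. `start`/`end` are 1-based inclusive
  forward-strand coordinates (`start <= end`); `strand` is `1` or
  `-1`.
* `merged_from` — original block ids this vertex stands for; more than
  one entry marks a merged block (then several rows per contig are
  allowed).  Omitted or empty means the block stands for itself.
* `length_nt` — representative length; defaults to the longest row.
* `sequences` — ordered: index 0 is the guide sequence, the rest are
  comparative sequences in genome order.  `vertices` is the contig's
  total order over block ids; all vertices must be distinct, the list
  at least 2 long, and comparative sequences must start and end on
  guide vertices.
* `color` — any SVG color token; assigned from the default palette
  (red guide, then green, purple, pink, brown, …) when omitted.

Serialization via `dumps_gmsa` is canonical (sorted keys, blocks
sorted by id), so `write(load(x))` is byte-identical for canonical
input.  `export_tsv` provides a flattened one-row-per-interval view
for spreadsheets; it is a convenience export, not an input format.

## MAF input

Standard `a`/`s`-line MAF.  Each `a` record becomes one block, each
`s` line one row; `src` is split at the first `.` into genome and
contig.  Strand-relative 0-based half-open coordinates are converted
to forward-strand 1-based inclusive ones, keeping the direction in
`strand`.  Per contig, the vertex sequence is the block order sorted
by forward start coordinate; the guide is selected with
`--guide GENOME:CONTIG` (default: the first row's contig).

## SVG output

Standalone SVG 1.1.  Stable element classes for downstream tooling:
`vertex` (plus `merged`), `seq-edge` (one polyline per sequence
adjacency, `data-seq`/`data-direction` attributes), `glyph`
(`dir-right|dir-left|dir-both`), `flag` (`flag-start|flag-end`).
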