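"""Domain model, native JSON dialect, MAF ingest, validation, and the
synthetic gMSA generator.

A *gMSA graph* is a directed multi-graph whose vertices are (merged)
alignment blocks and whose edges encode, per contig, the traversal order
of the blocks along that contig.  The graph is stored implicitly as an
ordered list of *vertex sequences* — one total order of block ids per
contig.  The first sequence is the *guide sequence* (the reference the
drawing is anchored on); the remaining sequences are *comparative
sequences* listed in decreasing relevance (the genome order).

Two structural rules make a gMSA graph drawable by the layout pipeline:

* every vertex sequence is a path of pairwise-distinct vertices of
  length >= 2, and
* every comparative sequence starts and ends on a vertex of the guide
  sequence (no loose ends).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "SequenceInterval",
    "AlignmentBlock",
    "VertexSequence",
    "GMSAGraph",
    "SyntheticParams",
    "Violation",
    "GmsaError",
    "load_gmsa",
    "loads_gmsa",
    "dump_gmsa",
    "dumps_gmsa",
    "load_maf",
    "validate",
    "generate_synthetic",
]

DEFAULT_PALETTE = ("red", "green", "purple", "pink", "brown", "teal", "olive",
                   "navy", "maroon", "darkorange", "steelblue", "darkcyan")


class GmsaError(ValueError):
    """Malformed or invalid gMSA input."""


@dataclass(frozen=True)
class SequenceInterval:
    """One aligned row of an alignment block.

    Coordinates are 1-based and inclusive on the forward strand;
    ``sigma`` is the reading direction (+1 forward, -1 reverse
    complement).
    """

    genome: str
    contig: str
    i: int
    j: int
    sigma: int = 1

    def __post_init__(self) -> None:
        if self.i > self.j:
            raise GmsaError(f"interval start {self.i} > end {self.j}")
        if self.i < 1:
            raise GmsaError(f"interval start {self.i} < 1 (coordinates are 1-based)")
        if self.sigma not in (1, -1):
            raise GmsaError(f"strand sigma must be +1 or -1, got {self.sigma}")

    @property
    def length(self) -> int:
        return self.j - self.i + 1

    @property
    def seq_name(self) -> str:
        return f"{self.genome}:{self.contig}"


@dataclass(frozen=True)
class AlignmentBlock:
    """A vertex of the gMSA graph: one or more aligned sequence intervals.

    ``merged_from`` lists the original block ids the vertex stands for;
    a length > 1 marks a *merged* block (a co-linear run collapsed into
    one vertex with no loss of adjacency information).
    """

    id: str
    rows: tuple[SequenceInterval, ...]
    merged_from: tuple[str, ...] = ()
    length_nt: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise GmsaError(f"block {self.id}: rows must be non-empty")
        if not self.merged_from:
            object.__setattr__(self, "merged_from", (self.id,))
        if self.length_nt <= 0:
            object.__setattr__(self, "length_nt", max(r.length for r in self.rows))

    @property
    def is_merged(self) -> bool:
        return len(self.merged_from) > 1

    def strands_of(self, seq_name: str) -> set[int]:
        """Set of reading directions this contig has inside the block."""
        return {r.sigma for r in self.rows if r.seq_name == seq_name}


@dataclass(frozen=True)
class VertexSequence:
    """One contig's total order over block ids (a path of distinct vertices)."""

    genome: str
    contig: str
    vertices: tuple[str, ...]
    color: str = ""

    @property
    def name(self) -> str:
        return f"{self.genome}:{self.contig}"

    @property
    def adjacencies(self) -> tuple[tuple[str, str], ...]:
        v = self.vertices
        return tuple((v[k], v[k + 1]) for k in range(len(v) - 1))

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class GMSAGraph:
    """An ordered set of vertex sequences over a shared block table.

    ``sequences[0]`` is the guide sequence; the rest are comparative
    sequences in genome order.  The multi-edge set is always derived
    from the sequences, never stored.
    """

    blocks: dict[str, AlignmentBlock]
    sequences: list[VertexSequence]

    @property
    def guide(self) -> VertexSequence:
        return self.sequences[0]

    @property
    def comparatives(self) -> list[VertexSequence]:
        return self.sequences[1:]

    def sequence(self, name: str) -> VertexSequence:
        for s in self.sequences:
            if s.name == name:
                return s
        raise KeyError(name)

    def multi_edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield (u, v, sequence name) for every adjacency of every sequence."""
        for s in self.sequences:
            for u, v in s.adjacencies:
                yield u, v, s.name

    def n_multi_edges(self) -> int:
        return sum(len(s) - 1 for s in self.sequences)

    def traversers(self, block_id: str) -> tuple[str, ...]:
        """Names of the sequences whose path visits ``block_id``, in genome order."""
        return tuple(s.name for s in self.sequences if block_id in s.vertices)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic gMSA generator.

    The generator emulates the structure of a bacterial-scale gMSA: a
    guide contig cut into ``n_guide_vertices`` blocks and
    ``n_comparative`` contigs derived from the guide by insertion,
    deletion and inversion events.
    """

    n_guide_vertices: int = 12
    n_comparative: int = 3
    p_insertion: float = 0.15
    p_deletion: float = 0.15
    p_inversion: float = 0.15
    max_insert_len: int = 3
    mean_block_nt: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_insertion", "p_deletion", "p_inversion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GmsaError(f"{name} must be in [0, 1], got {p}")
        if self.n_guide_vertices < 2:
            raise GmsaError("n_guide_vertices must be >= 2")
        if self.n_comparative < 0:
            raise GmsaError("n_comparative must be >= 0")
        if self.max_insert_len < 1:
            raise GmsaError("max_insert_len must be >= 1")


@dataclass(frozen=True)
class Violation:
    """One violated invariant, as data (validation never raises)."""

    kind: str
    where: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.where}: {self.detail}"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(g: GMSAGraph) -> list[Violation]:
    """Check every structural invariant of a gMSA graph.

    Returns an empty list iff the graph is valid.  Checked: block
    invariants, single hits (a contig appears at most once per
    unmerged block), sequences are distinct-vertex paths of length
    >= 2 referencing known blocks, sequence names are unique, and every
    comparative sequence is anchored on the guide at both ends.
    """
    out: list[Violation] = []
    for bid, b in g.blocks.items():
        if bid != b.id:
            out.append(Violation("block-id", bid, f"key {bid!r} != block id {b.id!r}"))
        if not b.is_merged:
            seen: set[str] = set()
            for r in b.rows:
                if r.seq_name in seen:
                    out.append(Violation(
                        "single-hit", bid,
                        f"contig {r.seq_name} occurs in more than one row"))
                seen.add(r.seq_name)

    if not g.sequences:
        out.append(Violation("no-sequences", "graph", "at least a guide sequence is required"))
        return out

    names = [s.name for s in g.sequences]
    for n in sorted({x for x in names if names.count(x) > 1}):
        out.append(Violation("duplicate-sequence", n, "sequence name occurs twice"))

    for s in g.sequences:
        if len(s) < 2:
            out.append(Violation("short-sequence", s.name,
                                 f"length {len(s)} < 2"))
        if len(set(s.vertices)) != len(s.vertices):
            dup = sorted({v for v in s.vertices if s.vertices.count(v) > 1})
            out.append(Violation("not-a-path", s.name,
                                 f"vertex revisited: {', '.join(dup)}"))
        for v in s.vertices:
            if v not in g.blocks:
                out.append(Violation("unknown-block", s.name,
                                     f"vertex {v!r} not in block table"))

    guide_set = set(g.guide.vertices)
    for s in g.comparatives:
        if not s.vertices:
            continue
        if s.vertices[0] not in guide_set:
            out.append(Violation("anchoring", s.name,
                                 f"first vertex {s.vertices[0]!r} not on the guide"))
        if s.vertices[-1] not in guide_set:
            out.append(Violation("anchoring", s.name,
                                 f"last vertex {s.vertices[-1]!r} not on the guide"))
    return out


def require_valid(g: GMSAGraph, context: str = "input") -> None:
    """Raise :class:`GmsaError` listing all violations, if any."""
    violations = validate(g)
    if violations:
        msg = "; ".join(str(v) for v in violations)
        raise GmsaError(f"invalid gMSA graph ({context}): {msg}")


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def _block_to_json(b: AlignmentBlock) -> dict:
    return {
        "id": b.id,
        "length_nt": b.length_nt,
        "merged_from": list(b.merged_from),
        "rows": [
            {"genome": r.genome, "contig": r.contig, "start": r.i,
             "end": r.j, "strand": r.sigma}
            for r in b.rows
        ],
    }


def _block_from_json(d: dict) -> AlignmentBlock:
    try:
        rows = tuple(
            SequenceInterval(r["genome"], r["contig"], int(r["start"]),
                             int(r["end"]), int(r.get("strand", 1)))
            for r in d["rows"]
        )
        return AlignmentBlock(
            id=str(d["id"]),
            rows=rows,
            merged_from=tuple(d.get("merged_from") or ()),
            length_nt=int(d.get("length_nt", 0)),
        )
    except KeyError as e:  # pragma: no cover - defensive
        raise GmsaError(f"block record missing field {e}") from None


def dumps_gmsa(g: GMSAGraph) -> str:
    """Serialize to the canonical JSON dialect (stable key and block order)."""
    doc = {
        "format": "gmsa-graph/1",
        "blocks": [_block_to_json(g.blocks[k]) for k in sorted(g.blocks)],
        "sequences": [
            {"genome": s.genome, "contig": s.contig, "color": s.color,
             "vertices": list(s.vertices)}
            for s in g.sequences
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def dump_gmsa(g: GMSAGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_gmsa(g))


def loads_gmsa(text: str, check: bool = True) -> GMSAGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise GmsaError(f"malformed JSON at line {e.lineno}, column {e.colno}: {e.msg}") from None
    if not isinstance(doc, dict) or "blocks" not in doc or "sequences" not in doc:
        raise GmsaError("document must be an object with 'blocks' and 'sequences'")
    blocks: dict[str, AlignmentBlock] = {}
    for k, rec in enumerate(doc["blocks"]):
        try:
            b = _block_from_json(rec)
        except GmsaError as e:
            raise GmsaError(f"blocks[{k}]: {e}") from None
        blocks[b.id] = b
    seqs = []
    palette = iter(DEFAULT_PALETTE)
    for k, rec in enumerate(doc["sequences"]):
        try:
            seqs.append(VertexSequence(
                genome=str(rec["genome"]), contig=str(rec.get("contig", "")),
                vertices=tuple(str(v) for v in rec["vertices"]),
                color=str(rec.get("color") or next(palette, "gray"))))
        except KeyError as e:
            raise GmsaError(f"sequences[{k}]: missing field {e}") from None
    g = GMSAGraph(blocks=blocks, sequences=seqs)
    if check:
        require_valid(g, "JSON input")
    return g


def export_tsv(g: GMSAGraph) -> str:
    """Flattened convenience view: one row per (block row)."""
    lines = ["block\tmerged_from\tlength_nt\tgenome\tcontig\tstart\tend\tstrand"]
    for bid in sorted(g.blocks):
        b = g.blocks[bid]
        for r in b.rows:
            lines.append("\t".join(map(str, (
                b.id, ",".join(b.merged_from), b.length_nt,
                r.genome, r.contig, r.i, r.j, r.sigma))))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MAF ingest
# ---------------------------------------------------------------------------

def load_maf(path, guide: str | None = None, check: bool = True) -> GMSAGraph:
    """Build a gMSA graph from a MAF file.

    Every ``a`` record becomes one alignment block; each ``s`` line one
    row.  MAF's 0-based half-open, strand-relative coordinates are
    converted to 1-based inclusive forward-strand coordinates, keeping
    the reading direction in ``sigma``.  Each contig's vertex sequence
    is the order of its blocks sorted by forward start coordinate; the
    guide (``"genome:contig"``, default: contig of the first row of the
    first block) is listed first, the rest in order of first appearance.
    """
    from Bio import AlignIO

    blocks: dict[str, AlignmentBlock] = {}
    per_contig: dict[str, list[tuple[int, str]]] = {}
    order_seen: list[str] = []
    for k, aln in enumerate(AlignIO.parse(str(path), "maf")):
        rows = []
        for rec in aln:
            src = rec.id
            genome, _, contig = src.partition(".")
            if not contig:
                genome, contig = src, src
            ann = rec.annotations
            start, size, strand = int(ann["start"]), int(ann["size"]), int(ann["strand"])
            if size < 1:
                raise GmsaError(f"MAF block {k}: row {src} has size {size} < 1")
            if strand >= 0:
                fwd_start = start
                sigma = 1
            else:
                fwd_start = int(ann["srcSize"]) - start - size
                sigma = -1
            rows.append(SequenceInterval(genome, contig, fwd_start + 1,
                                         fwd_start + size, sigma))
        if not rows:
            raise GmsaError(f"MAF block {k} has no 's' rows")
        bid = f"b{k}"
        blocks[bid] = AlignmentBlock(id=bid, rows=tuple(rows))
        for r in rows:
            per_contig.setdefault(r.seq_name, []).append((r.i, bid))
            if r.seq_name not in order_seen:
                order_seen.append(r.seq_name)
    if not blocks:
        raise GmsaError("MAF file contains no alignment blocks")

    if guide is None:
        guide = order_seen[0]
    if guide not in per_contig:
        raise GmsaError(f"guide contig {guide!r} not present in MAF "
                        f"(have: {', '.join(order_seen)})")
    names = [guide] + [n for n in order_seen if n != guide]
    seqs = []
    for idx, name in enumerate(names):
        genome, _, contig = name.partition(":")
        vertices = tuple(bid for _, bid in sorted(per_contig[name]))
        seqs.append(VertexSequence(genome, contig, vertices,
                                   color=DEFAULT_PALETTE[idx % len(DEFAULT_PALETTE)]))
    g = GMSAGraph(blocks=blocks, sequences=seqs)
    if check:
        require_valid(g, "MAF input")
    return g


def load_gmsa(path, format: str | None = None, guide: str | None = None,
              check: bool = True) -> GMSAGraph:
    """Load a gMSA graph from the native JSON dialect or a MAF file.

    ``format`` is ``"json"`` or ``"maf"``; if omitted it is inferred
    from the file suffix.
    """
    p = str(path)
    if format is None:
        format = "maf" if p.lower().endswith(".maf") else "json"
    if format == "json":
        with open(p) as fh:
            return loads_gmsa(fh.read(), check=check)
    if format == "maf":
        return load_maf(p, guide=guide, check=check)
    raise GmsaError(f"unknown format {format!r} (expected 'json' or 'maf')")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

def _guide_blocks(rng: random.Random, p: SyntheticParams) -> tuple[dict[str, AlignmentBlock], list[str]]:
    blocks: dict[str, AlignmentBlock] = {}
    ids = []
    pos = 1
    for k in range(p.n_guide_vertices):
        length = max(1, int(rng.expovariate(1.0 / p.mean_block_nt)) + 1)
        bid = f"b{k}"
        blocks[bid] = AlignmentBlock(
            id=bid,
            rows=(SequenceInterval("G0", "c0", pos, pos + length - 1, 1),),
            length_nt=length)
        ids.append(bid)
        pos += length
    return blocks, ids


def generate_synthetic(p: SyntheticParams) -> GMSAGraph:
    """Generate a random valid gMSA graph.

    The guide is a fresh path of ``n_guide_vertices`` blocks on contig
    ``G0:c0``.  Each comparative contig is derived from the guide by,
    in order: per-vertex deletion (probability ``p_deletion``, never
    below 2 surviving guide vertices), per-gap insertion of 1..
    ``max_insert_len`` novel blocks (probability ``p_insertion``), and
    inversion of a random sub-run (probability ``p_inversion``,
    flipping the strand of the affected rows).  Ends are trimmed back
    to guide vertices so the anchoring rule holds.  Deterministic for a
    fixed seed.
    """
    rng = random.Random(p.seed)
    blocks, guide_ids = _guide_blocks(rng, p)
    seqs = [VertexSequence("G0", "c0", tuple(guide_ids), DEFAULT_PALETTE[0])]

    for c in range(p.n_comparative):
        genome, contig = f"G{c + 1}", f"c{c + 1}"
        name = f"{genome}:{contig}"
        # deletions: keep at least 2 guide vertices
        kept = [b for b in guide_ids if rng.random() >= p.p_deletion]
        if len(kept) < 2:
            kept = sorted(rng.sample(guide_ids, 2), key=guide_ids.index)
        # insertions: novel vertices between consecutive kept blocks
        path: list[tuple[str, int]] = []  # (block id, sigma)
        for k, bid in enumerate(kept):
            path.append((bid, 1))
            if k < len(kept) - 1 and rng.random() < p.p_insertion:
                for m in range(rng.randint(1, p.max_insert_len)):
                    nid = f"i{c}_{k}_{m}"
                    path.append((nid, 1))
        # inversion of one random sub-run (strand flips with the order)
        if len(path) >= 2 and rng.random() < p.p_inversion:
            lo = rng.randrange(len(path) - 1)
            hi = rng.randrange(lo + 1, len(path))
            path[lo:hi + 1] = [(bid, -s) for bid, s in reversed(path[lo:hi + 1])]
        # trim ends back onto the guide (anchoring)
        guide_pos = [k for k, (bid, _) in enumerate(path) if bid.startswith("b")]
        if len(guide_pos) < 2:
            # degenerate draw: fall back to the two outermost kept guide blocks
            path = [(kept[0], 1), (kept[-1], 1)]
            guide_pos = [0, 1]
        path = path[guide_pos[0]:guide_pos[-1] + 1]

        # materialize rows along the comparative contig's own coordinates
        pos = 1
        verts = []
        for bid, sigma in path:
            if bid in blocks:
                length = blocks[bid].length_nt
            else:
                length = max(1, int(rng.expovariate(1.0 / p.mean_block_nt)) + 1)
            row = SequenceInterval(genome, contig, pos, pos + length - 1, sigma)
            pos += length
            if bid in blocks:
                b = blocks[bid]
                blocks[bid] = replace(b, rows=b.rows + (row,))
            else:
                blocks[bid] = AlignmentBlock(id=bid, rows=(row,), length_nt=length)
            verts.append(bid)
        seqs.append(VertexSequence(
            genome, contig, tuple(verts),
            DEFAULT_PALETTE[(c + 1) % len(DEFAULT_PALETTE)]))

    # drop novel blocks orphaned by end trimming
    used = {v for s in seqs for v in s.vertices}
    blocks = {k: v for k, v in blocks.items() if k in used}
    g = GMSAGraph(blocks=blocks, sequences=seqs)
    require_valid(g, f"synthetic graph (seed {p.seed})")
    return g
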