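"""Shared fixtures: hand-built and synthetic gMSA graphs."""

from __future__ import annotations

import pytest

from gmsalayout import (AlignmentBlock, GMSAGraph, SequenceInterval,
                        SyntheticParams, VertexSequence, generate_synthetic)
from gmsalayout.model_io import DEFAULT_PALETTE


def make_graph(*orders: list[str], strands: dict[tuple[str, str], int] | None = None,
               lengths: dict[str, int] | None = None) -> GMSAGraph:
    """Build a gMSA graph from per-contig vertex orders.

    ``orders[0]`` is the guide.  Each contig gets consecutive forward
    coordinates along its own axis; ``strands[(seq_name, block)]``
    overrides the reading direction of one row.
    """
    strands = strands or {}
    lengths = lengths or {}
    rows: dict[str, list[SequenceInterval]] = {}
    seqs = []
    for idx, order in enumerate(orders):
        genome, contig = f"G{idx}", f"c{idx}"
        name = f"{genome}:{contig}"
        pos = 1
        for v in order:
            ln = lengths.get(v, 100)
            rows.setdefault(v, []).append(SequenceInterval(
                genome, contig, pos, pos + ln - 1,
                strands.get((name, v), 1)))
            pos += ln
        seqs.append(VertexSequence(genome, contig, tuple(order),
                                   DEFAULT_PALETTE[idx % len(DEFAULT_PALETTE)]))
    blocks = {v: AlignmentBlock(id=v, rows=tuple(r), length_nt=lengths.get(v, 100))
              for v, r in rows.items()}
    return GMSAGraph(blocks=blocks, sequences=seqs)


@pytest.fixture
def guide_only() -> GMSAGraph:
    return make_graph(["a", "b", "c", "d", "e"])


@pytest.fixture
def diamond() -> GMSAGraph:
    """Guide (a,b,c) with one insertion bypath and one reversed bypath."""
    return make_graph(["a", "b", "c"], ["a", "x", "c"], ["c", "y", "a"])


@pytest.fixture
def small_synthetic() -> GMSAGraph:
    return generate_synthetic(SyntheticParams(
        n_guide_vertices=12, n_comparative=4, p_insertion=0.3,
        p_deletion=0.2, p_inversion=0.3, seed=7))
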