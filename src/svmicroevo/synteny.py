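"""Perfectly-collinear gene-order blocks and SV polarization.

Because any gap or mismatch breaks an alignment in the targeted regime
(prohibitively high penalties), block finding reduces to exact detection of
maximal runs where ortholog indices advance by +1 in both genomes (or -1
throughout, for inversions).  Each gene belongs to at most one block.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

from .core_io import CollinearBlock, GeneModel, SVCall, overlap_length

__all__ = ["collinear_blocks", "polarize_svs"]


def collinear_blocks(order_a: Sequence[GeneModel], order_b: Sequence[str],
                     ortholog_map: Mapping[str, str], min_len: int = 2,
                     allow_reversed: bool = True) -> list[CollinearBlock]:
    """Maximal collinear runs between genome A (gene models, in genome
    order) and genome B (gene ids in genome order).

    ortholog_map must be one-to-one over the genes it covers; genes without
    an ortholog break runs.  Runs must advance +1 in B throughout, or -1
    throughout when allow_reversed is set.  Runs shorter than min_len are
    dropped.  Block span_a goes from the first gene's start to the last
    gene's end in A coordinates.
    """
    a_ids = [g.gene_id for g in order_a]
    if len(set(a_ids)) != len(a_ids):
        raise ValueError("duplicate gene in order_a")
    if len(set(order_b)) != len(order_b):
        raise ValueError("duplicate gene in order_b")
    mapped_targets = [ortholog_map[g] for g in ortholog_map]
    if len(set(mapped_targets)) != len(mapped_targets):
        raise ValueError("ortholog_map is not one-to-one")

    pos_b = {gid: i for i, gid in enumerate(order_b)}
    # B position of each A gene; None where no usable ortholog
    pos = [pos_b.get(ortholog_map.get(g.gene_id)) for g in order_a]

    blocks: list[CollinearBlock] = []
    n = len(order_a)
    i = 0
    while i < n:
        if pos[i] is None:
            i += 1
            continue
        j = i + 1
        direction = 0
        while j < n and pos[j] is not None:
            d = pos[j] - pos[j - 1]
            if d == 1 and direction in (0, 1):
                direction = 1
            elif d == -1 and direction in (0, -1) and allow_reversed:
                direction = -1
            else:
                break
            j += 1
        if j - i >= min_len:
            members = order_a[i:j]
            blocks.append(CollinearBlock(
                pairs=tuple((g.gene_id, ortholog_map[g.gene_id]) for g in members),
                span_a=(members[0].contig, members[0].start, members[-1].end),
                orientation="reversed" if direction == -1 else "same"))
            i = j
        else:
            i += 1
    return blocks


def polarize_svs(calls: Sequence[SVCall], blocks: Sequence[CollinearBlock],
                 min_overlap: int = 1,
                 min_overlap_frac: float = 0.0) -> list[SVCall]:
    """Set each call's polarized flag from overlap with the union of block
    spans.  A call is polarized when it overlaps by >= min_overlap bases
    and by >= min_overlap_frac of its own length."""
    spans = [b.span_a for b in blocks]
    out = []
    for c in calls:
        ov = 0
        for contig, s, e in spans:
            if contig == c.contig:
                ov += overlap_length(c.start, c.end, s, e)
        ok = ov >= min_overlap and ov >= min_overlap_frac * c.length
        out.append(replace(c, polarized="true" if ok else "false"))
    return out
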