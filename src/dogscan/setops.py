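"""Combine DoG annotations across samples: union and intersection.

Both operations are keyed by gene identifier — every DoG is anchored to
a gene by construction — and combine extents with the *most downstream*
rule: for a + strand gene the largest end wins, for a - strand gene the
smallest start, while the gene-3'-end anchor coordinate is preserved.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Sequence, Tuple

from .genomic_model import DoGRecord

__all__ = ["union_dogs", "common_dogs"]


def _index_sets(
    sets: Sequence[Sequence[DoGRecord]],
) -> List[Dict[str, DoGRecord]]:
    indexed: List[Dict[str, DoGRecord]] = []
    for i, records in enumerate(sets):
        by_gene: Dict[str, DoGRecord] = {}
        for rec in records:
            if rec.gene_id in by_gene:
                raise ValueError(
                    f"set {i}: duplicate gene_id {rec.gene_id!r} within one annotation"
                )
            by_gene[rec.gene_id] = rec
        indexed.append(by_gene)
    return indexed


def _combine(records: List[DoGRecord], rule: str) -> DoGRecord:
    first = records[0]
    for rec in records[1:]:
        if rec.strand != first.strand or rec.chrom != first.chrom:
            raise ValueError(
                f"gene {first.gene_id!r} has conflicting placement across files: "
                f"{first.chrom}{first.strand} vs {rec.chrom}{rec.strand}"
            )
    if first.strand == "+":
        start = min(r.start for r in records)  # anchor (gene 3' end) side
        ends = [r.end for r in records]
        end = max(ends) if rule == "max" else min(ends)
    else:
        end = max(r.end for r in records)
        starts = [r.start for r in records]
        start = min(starts) if rule == "max" else max(starts)
    return DoGRecord(first.chrom, start, end, first.strand, first.gene_id)


def union_dogs(sets: Sequence[Sequence[DoGRecord]]) -> List[DoGRecord]:
    """Merge DoG sets: one record per gene present in *any* set, its end
    pushed to the most downstream coordinate observed."""
    if not sets:
        raise ValueError("at least one DoG set is required")
    indexed = _index_sets(sets)
    genes = sorted({g for s in indexed for g in s})
    out = [
        _combine([s[g] for s in indexed if g in s], rule="max") for g in genes
    ]
    out.sort(key=lambda d: (d.chrom, d.start, d.end))
    return out


def common_dogs(
    sets: Sequence[Sequence[DoGRecord]], combine: str = "max"
) -> List[DoGRecord]:
    """Intersect DoG sets: one record per gene present in *all* sets.

    Ends are combined with the most-downstream rule by default
    (``combine="max"``); ``combine="min"`` keeps the minimal common
    extent instead.
    """
    if len(sets) < 2:
        raise ValueError("intersection requires at least two DoG sets")
    if combine not in ("max", "min"):
        raise ValueError(f"combine must be 'max' or 'min', got {combine!r}")
    indexed = _index_sets(sets)
    genes = sorted(set.intersection(*(set(s) for s in indexed)))
    out = [_combine([s[g] for s in indexed], rule=combine) for g in genes]
    out.sort(key=lambda d: (d.chrom, d.start, d.end))
    return out
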