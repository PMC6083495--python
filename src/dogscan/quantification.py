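"""DoG expression quantification as RPKM.

RPKM = reads per kilobase of DoG per million mapped reads:

    rpkm = count / ((length / 1000) * (total_mapped / 1e6))

``count`` is the number of alignment records (mates count individually)
with >= 1 bp block overlap with the DoG, strand-matched for stranded
libraries. ``total_mapped`` is the mapped-read count of the
preprocessed, downsampled sample, so cross-sample RPKMs share the
normalization depth equalization was designed to create. Genic-read
removal is a discovery-time filter only: a read overlapping both a gene
locus and a DoG still counts for the DoG (an ``exclude_genic`` toggle
is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from . import formats_io
from .genomic_model import AlignmentRecord, DoGRecord
from .loci_builder import LociAnnotation
from .preprocess import LibrarySpec, normalize_strand

__all__ = ["DoGExpression", "count_dog_reads", "compute_rpkm"]


@dataclass(frozen=True)
class DoGExpression:
    record: DoGRecord
    read_count: int
    total_mapped: int
    rpkm: float


def _overlaps(record: AlignmentRecord, dog: DoGRecord) -> bool:
    for s, e in record.blocks:
        if s < dog.end and e > dog.start:
            return True
    return False


def count_dog_reads(
    records: Sequence[AlignmentRecord], dog: DoGRecord, spec: LibrarySpec
) -> int:
    """Reads with >= 1 bp block overlap with the DoG interval; effective
    strand must match for stranded libraries. Each mate counts once."""
    stranded = spec.stranded
    n = 0
    for rec in records:
        if rec.chrom != dog.chrom:
            continue
        if stranded and rec.strand != dog.strand:
            continue
        if _overlaps(rec, dog):
            n += 1
    return n


def compute_rpkm(
    sample: Union[str, Path, Sequence[AlignmentRecord]],
    dogs: Sequence[DoGRecord],
    spec: LibrarySpec = LibrarySpec("single", "forward"),
    total_mapped: Optional[int] = None,
    exclude_genic: bool = False,
    loci: Optional[LociAnnotation] = None,
    drop_duplicates: bool = False,
) -> List[DoGExpression]:
    """Per-DoG RPKM for one sample, in the input annotation order.

    ``sample`` is a SAM/BAM path or normalized records (then
    ``total_mapped`` is required). With ``exclude_genic`` the discovery
    filter is reapplied before counting (requires ``loci``).
    """
    if not dogs:
        raise ValueError("DoG annotation is empty")
    if isinstance(sample, (str, Path)):
        raw, total = formats_io.read_alignments(sample, drop_duplicates=drop_duplicates)
        records: Sequence[AlignmentRecord] = [normalize_strand(r, spec) for r in raw]
        if total_mapped is None:
            total_mapped = total
    else:
        records = list(sample)
        if total_mapped is None:
            raise ValueError("total_mapped is required for in-memory records")
    if total_mapped == 0:
        raise ValueError("total_mapped is zero; cannot normalize RPKM")
    if exclude_genic:
        if loci is None:
            raise ValueError("exclude_genic requires a loci annotation")
        from .discovery import filter_genic_reads

        records = list(filter_genic_reads(records, loci, stranded=spec.stranded))

    # bucket reads per chromosome once; per-DoG scan stays linear
    by_chrom: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    out: List[DoGExpression] = []
    for dog in dogs:
        count = count_dog_reads(by_chrom.get(dog.chrom, ()), dog, spec)
        rpkm = count / ((dog.length / 1000.0) * (total_mapped / 1_000_000.0))
        out.append(
            DoGExpression(record=dog, read_count=count, total_mapped=total_mapped, rpkm=rpkm)
        )
    return out
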