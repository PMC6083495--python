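"""Readthrough (DoG) discovery.

A DoG is a region of continuous read coverage immediately 3' of an
annotated gene end. Discovery proceeds per sample:

1. genic reads — any read with a block overlapping a gene locus — are
   removed, so only intergenic signal is considered;
2. a gene yields a *candidate* when the coverage breadth over the
   initial ``min_dog_len`` bases downstream of its 3' end is at least
   ``min_dog_cov``;
3. candidates are elongated in overlapping running windows
   (``window_len`` long, advancing by ``window_step``) until a window's
   coverage breadth drops below ``min_dog_cov``;
4. extents are limited by the nearest 3' neighboring gene (same strand
   for stranded libraries, either strand for unstranded ones), and
   genes whose downstream room is below ``min_dog_len`` are discarded.

"Coverage" throughout is breadth: the fraction of bases covered by at
least one aligned block, regardless of depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from intervaltree import IntervalTree

from . import formats_io
from .genomic_model import (
    AlignmentRecord,
    DoGParams,
    DoGRecord,
    GeneLocus,
    three_prime_end,
)
from .loci_builder import LociAnnotation
from .preprocess import LibrarySpec, normalize_strand

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageIndex",
    "EligibleGene",
    "filter_genic_reads",
    "coverage_fraction",
    "detect_candidate",
    "elongate",
    "eligible_genes",
    "discover_dogs",
]


class CoverageIndex:
    """Per-base boolean coverage by chromosome and strand.

    Records whose strand is non-informative (unstranded libraries)
    contribute to both strands, so strand-agnostic queries see them and
    strand-specific queries are only meaningful for stranded data.
    """

    def __init__(self, chrom_lengths: Dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._cov: Dict[Tuple[str, str], np.ndarray] = {}

    def _array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        arr = self._cov.get(key)
        if arr is None:
            arr = np.zeros(self.chrom_lengths[chrom], dtype=bool)
            self._cov[key] = arr
        return arr

    def add(self, record: AlignmentRecord) -> None:
        if record.chrom not in self.chrom_lengths:
            return
        strands = (record.strand,) if record.strand_informative else ("+", "-")
        for strand in strands:
            arr = self._array(record.chrom, strand)
            for s, e in record.blocks:
                arr[max(s, 0):min(e, arr.size)] = True

    def covered_bases(self, chrom: str, start: int, end: int, strand: str) -> int:
        if end <= start:
            return 0
        if strand == "any":
            plus = self._cov.get((chrom, "+"))
            minus = self._cov.get((chrom, "-"))
            if plus is None and minus is None:
                return 0
            if plus is None:
                return int(minus[start:end].sum())
            if minus is None:
                return int(plus[start:end].sum())
            return int((plus[start:end] | minus[start:end]).sum())
        arr = self._cov.get((chrom, strand))
        return 0 if arr is None else int(arr[start:end].sum())

    @classmethod
    def from_records(
        cls, records: Iterable[AlignmentRecord], chrom_lengths: Dict[str, int]
    ) -> "CoverageIndex":
        index = cls(chrom_lengths)
        for rec in records:
            index.add(rec)
        return index


def coverage_fraction(
    index: CoverageIndex, chrom: str, interval: Tuple[int, int], strand: str = "any"
) -> float:
    """Fraction of positions in ``interval`` covered by >= 1 aligned
    block of a strand-matching record (``strand="any"`` ignores strand).
    Splice gaps contribute no coverage."""
    start, end = interval
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    return index.covered_bases(chrom, start, end, strand) / (end - start)


def _genic_trees(loci: LociAnnotation) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for locus in loci:
        trees.setdefault((locus.chrom, locus.strand), IntervalTree()).addi(
            locus.start, locus.end
        )
    return trees


def filter_genic_reads(
    records: Iterable[AlignmentRecord],
    loci: LociAnnotation,
    stranded: bool,
) -> Iterable[AlignmentRecord]:
    """Drop every record with >= 1 bp block overlap with a gene locus.

    Stranded mode only tests loci on the record's effective strand;
    unstranded mode tests loci on either strand. Surviving records are
    yielded unchanged.
    """
    trees = _genic_trees(loci)

    def overlaps(record: AlignmentRecord) -> bool:
        strands = (record.strand,) if stranded else ("+", "-")
        for strand in strands:
            tree = trees.get((record.chrom, strand))
            if tree is None:
                continue
            for s, e in record.blocks:
                if tree.overlaps(s, e):
                    return True
        return False

    for record in records:
        if not overlaps(record):
            yield record


@dataclass(frozen=True)
class EligibleGene:
    """A gene with enough downstream room to host a DoG.

    ``limit`` is the coordinate beyond which a DoG may not extend (the
    nearest 3' neighbor's boundary, or the chromosome boundary);
    ``room`` the strand-oriented distance from the 3' end to it.
    """

    locus: GeneLocus
    room: int
    limit: int


def eligible_genes(
    loci: LociAnnotation,
    chrom_lengths: Dict[str, int],
    params: DoGParams,
    stranded: bool,
) -> List[EligibleGene]:
    """Genes whose downstream room reaches ``min_dog_len``.

    Room is bounded by the nearest 3' neighbor (same strand when
    stranded, any strand when unstranded — the conservative choice) and
    by the chromosome end, the degenerate neighbor.
    """
    out: List[EligibleGene] = []
    for locus in loci:
        chrom_len = chrom_lengths.get(locus.chrom)
        if chrom_len is None:
            continue
        q3p = three_prime_end(locus)
        neighbor = loci.nearest_downstream_neighbor(locus, stranded=stranded)
        if locus.strand == "+":
            limit = chrom_len if neighbor is None else min(neighbor, chrom_len)
            room = max(0, limit - q3p)
        else:
            limit = 0 if neighbor is None else max(neighbor, 0)
            room = max(0, q3p - limit)
        if room >= params.min_dog_len:
            out.append(EligibleGene(locus=locus, room=room, limit=limit))
    return out


def detect_candidate(
    gene: EligibleGene,
    params: DoGParams,
    reads: CoverageIndex,
    strand: Optional[str] = None,
) -> Optional[Tuple[int, int]]:
    """Initial-interval test: the ``min_dog_len`` bases downstream of
    the 3' end must reach ``min_dog_cov`` coverage breadth (inclusive).

    Returns the provisional extent, or ``None``.
    """
    locus = gene.locus
    q3p = three_prime_end(locus)
    if locus.strand == "+":
        interval = (q3p, q3p + params.min_dog_len)
    else:
        interval = (q3p - params.min_dog_len, q3p)
    query_strand = strand if strand is not None else locus.strand
    frac = coverage_fraction(reads, locus.chrom, interval, query_strand)
    return interval if frac >= params.min_dog_cov else None


def elongate(
    candidate: Tuple[int, int],
    gene: EligibleGene,
    params: DoGParams,
    reads: CoverageIndex,
    strand: Optional[str] = None,
) -> DoGRecord:
    """Extend a candidate 3'-ward in overlapping running windows.

    Windows of ``window_len`` advance by ``window_step`` from the
    downstream edge of the initial interval; while a window reaches
    ``min_dog_cov`` the DoG end moves to its downstream edge. The scan
    stops at the first failing window or at the neighbor limit; the
    final extent is clipped to the limit.
    """
    locus = gene.locus
    query_strand = strand if strand is not None else locus.strand
    cov = params.min_dog_cov
    win, step = params.window_len, params.window_step
    if locus.strand == "+":
        anchor = candidate[0]
        end = candidate[1]
        ws = end
        while True:
            we = ws + win
            if we > gene.limit:
                we = gene.limit
                if we > ws and coverage_fraction(reads, locus.chrom, (ws, we), query_strand) >= cov:
                    end = gene.limit
                break
            if coverage_fraction(reads, locus.chrom, (ws, we), query_strand) >= cov:
                end = we
                ws += step
            else:
                break
        return DoGRecord(locus.chrom, anchor, min(end, gene.limit), "+", locus.gene_id)
    anchor = candidate[1]
    start = candidate[0]
    we = start
    while True:
        ws = we - win
        if ws < gene.limit:
            ws = gene.limit
            if we > ws and coverage_fraction(reads, locus.chrom, (ws, we), query_strand) >= cov:
                start = gene.limit
            break
        if coverage_fraction(reads, locus.chrom, (ws, we), query_strand) >= cov:
            start = ws
            we -= step
        else:
            break
    return DoGRecord(locus.chrom, max(start, gene.limit), anchor, "-", locus.gene_id)


def _check_chrom_names(loci: LociAnnotation, chrom_lengths: Dict[str, int]) -> None:
    loci_chroms = {l.chrom for l in loci}
    aln_chroms = set(chrom_lengths)
    if loci_chroms and aln_chroms and not (loci_chroms & aln_chroms):
        example_l = sorted(loci_chroms)[0]
        example_a = sorted(aln_chroms)[0]
        raise ValueError(
            "no chromosome name is shared between the loci annotation "
            f"({example_l!r}, ...) and the alignment file ({example_a!r}, ...); "
            "rename one naming scheme (e.g. '1' <-> 'chr1') so they match"
        )


def discover_dogs(
    sample: Union[str, Path, Sequence[AlignmentRecord]],
    loci: LociAnnotation,
    params: DoGParams = DoGParams(),
    spec: LibrarySpec = LibrarySpec("single", "forward"),
    chrom_lengths: Optional[Dict[str, int]] = None,
    drop_duplicates: bool = False,
) -> List[DoGRecord]:
    """Call DoGs for one preprocessed sample.

    ``sample`` is a SAM/BAM path (strand-normalized on the fly using
    ``spec``) or an already-normalized record sequence (then
    ``chrom_lengths`` is required). Duplicate-flagged records are kept
    unless ``drop_duplicates``. At most one DoG per gene; output sorted
    by (chrom, start).
    """
    if isinstance(sample, (str, Path)):
        raw, _total = formats_io.read_alignments(sample, drop_duplicates=drop_duplicates)
        records = [normalize_strand(r, spec) for r in raw]
        chrom_lengths = formats_io.chromosome_lengths(sample)
    else:
        records = list(sample)
        if chrom_lengths is None:
            raise ValueError("chrom_lengths is required for in-memory records")
    _check_chrom_names(loci, chrom_lengths)
    stranded = spec.stranded
    nongenic = list(filter_genic_reads(records, loci, stranded=stranded))
    index = CoverageIndex.from_records(nongenic, chrom_lengths)
    dogs: List[DoGRecord] = []
    strand_query = None if stranded else "any"
    for gene in eligible_genes(loci, chrom_lengths, params, stranded=stranded):
        candidate = detect_candidate(gene, params, index, strand=strand_query)
        if candidate is None:
            continue
        dogs.append(elongate(candidate, gene, params, index, strand=strand_query))
    dogs.sort(key=lambda d: (d.chrom, d.start, d.end))
    logger.info("called %d DoGs from %d non-genic reads", len(dogs), len(nongenic))
    return dogs
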