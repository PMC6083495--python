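"""Readers and writers: GTF annotations, BED6 intervals, SAM/BAM
alignments and the tab-delimited expression table.

Coordinates are converted to the package-wide 0-based half-open
convention on read (GTF is 1-based closed; BED and pysam already are
half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Type, Union

import pysam
from gffutils.feature import feature_from_line

from .genomic_model import DoGRecord, GeneLocus

logger = logging.getLogger(__name__)

__all__ = [
    "GtfRecord",
    "RawAlignment",
    "read_gtf",
    "read_bed",
    "write_bed",
    "read_alignments",
    "write_expression_table",
    "read_expression_table",
]

EXPRESSION_COLUMNS = ("chrom", "start", "end", "gene_id", "strand", "dog_length", "rpkm")


@dataclass(frozen=True)
class GtfRecord:
    """One GTF feature reduced to the fields the loci builder needs."""

    chrom: str
    feature_type: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    gene_id: str
    transcript_id: Optional[str]


def _first_attr(feature, *keys: str) -> Optional[str]:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


def read_gtf(path: Union[str, Path]) -> Iterator[GtfRecord]:
    """Stream annotation records from a GTF file.

    Gene identity is taken from the ``gene_id`` attribute, falling back
    to ``gene_name``. Features without a usable identifier or without a
    definite strand are skipped with a warning; syntactically malformed
    lines raise ``ValueError`` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise ValueError(
                    f"{path}:{lineno}: malformed GTF line: expected 9 "
                    f"tab-separated fields, got {line.count(chr(9)) + 1}"
                )
            try:
                feature = feature_from_line(line, strict=False)
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise ValueError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            gene_id = _first_attr(feature, "gene_id", "gene_name")
            if gene_id is None:
                logger.warning("%s:%d: no gene_id/gene_name attribute; skipped", path, lineno)
                continue
            if feature.strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: feature for %s has strand %r; skipped",
                    path, lineno, gene_id, feature.strand,
                )
                continue
            yield GtfRecord(
                chrom=feature.seqid,
                feature_type=feature.featuretype,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand,
                gene_id=gene_id,
                transcript_id=_first_attr(feature, "transcript_id"),
            )


def read_bed(
    path: Union[str, Path],
    cls: Type = DoGRecord,
) -> List:
    """Read a BED6 file into ``cls`` records (``DoGRecord`` by default,
    ``GeneLocus`` for loci files). The name column carries the gene id;
    the score column is ignored. ``track``/``browser``/comment header
    lines are tolerated.
    """
    path = Path(path)
    out: List = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 required (chrom, start, end, name, "
                    f"score, strand); got {len(fields)} columns — strand column missing"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if cls is GeneLocus:
                out.append(GeneLocus(chrom, int(start), int(end), strand, name))
            else:
                out.append(cls(chrom, int(start), int(end), strand, name))
    return out


def write_bed(
    records: Iterable[Union[DoGRecord, GeneLocus]], path: Union[str, Path]
) -> None:
    """Write BED6, sorted by (chrom, start); name = gene_id, score = 0."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.gene_id))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class RawAlignment:
    """A mapped record before protocol (strand) normalization."""

    chrom: str
    blocks: Tuple[Tuple[int, int], ...]
    mapped_strand: str
    is_paired: bool
    mate_index: Optional[int]  # 1, 2 or None
    query_name: str


def aligned_blocks(read: "pysam.AlignedSegment") -> Tuple[Tuple[int, int], ...]:
    """Reference blocks of a read, split only at skip (N) operations.

    Deletions stay inside a block (they consume reference but represent
    alignment, not splicing), so coverage is contiguous across them.
    """
    blocks: List[Tuple[int, int]] = []
    pos = read.reference_start
    block_start = pos
    for op, length in read.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
        elif op == 3:  # N: splice gap
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        # I, S, H, P consume no reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return tuple(blocks)


def _check_sorted(af: "pysam.AlignmentFile", path: Path) -> None:
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so is not None and so != "coordinate":
        raise ValueError(
            f"{path}: alignments are not coordinate-sorted (SO={so}); "
            f"run `samtools sort` (and `samtools index`) first"
        )


def read_alignments(
    path: Union[str, Path], drop_duplicates: bool = False
) -> Tuple[List[RawAlignment], int]:
    """Read mapped records from a coordinate-sorted SAM/BAM file.

    Returns ``(records, total_mapped)``. Unmapped, secondary and
    supplementary records are excluded; duplicate-flagged records are
    kept unless ``drop_duplicates``. Spliced alignments are decomposed
    into reference blocks.
    """
    path = Path(path)
    records: List[RawAlignment] = []
    total_mapped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        _check_sorted(af, path)
        last_pos: dict = {}
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            total_mapped += 1
            chrom = read.reference_name
            prev = last_pos.get(chrom, -1)
            if read.reference_start < prev:
                raise ValueError(
                    f"{path}: alignments are not coordinate-sorted at {chrom}:"
                    f"{read.reference_start}; run `samtools sort` and "
                    f"`samtools index` first"
                )
            last_pos[chrom] = read.reference_start
            mate_index: Optional[int] = None
            if read.is_paired:
                mate_index = 1 if read.is_read1 else 2
            records.append(
                RawAlignment(
                    chrom=chrom,
                    blocks=aligned_blocks(read),
                    mapped_strand="-" if read.is_reverse else "+",
                    is_paired=read.is_paired,
                    mate_index=mate_index,
                    query_name=read.query_name or "",
                )
            )
    return records, total_mapped


def chromosome_lengths(path: Union[str, Path]) -> dict:
    """Chromosome name → length, from the alignment-file header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        return dict(zip(af.references, af.lengths))


# ---------------------------------------------------------------------------
# Expression table


def write_expression_table(
    rows: Sequence, path: Union[str, Path], comments: Sequence[str] = ()
) -> None:
    """Write the tab-delimited expression table.

    ``rows`` are objects with ``record`` (a DoGRecord) and ``rpkm``
    attributes, or ``(chrom, start, end, gene_id, strand, length, rpkm)``
    tuples. RPKM is printed with 4 decimal places. Optional ``comments``
    are emitted as leading ``#`` lines.
    """
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for row in rows:
            if hasattr(row, "record"):
                r = row.record
                values = (r.chrom, r.start, r.end, r.gene_id, r.strand, r.length, row.rpkm)
            else:
                values = tuple(row)
            chrom, start, end, gene_id, strand, length, rpkm = values
            fh.write(
                f"{chrom}\t{start}\t{end}\t{gene_id}\t{strand}\t{length}\t{rpkm:.4f}\n"
            )


def read_expression_table(path: Union[str, Path]):
    """Read an expression table back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
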