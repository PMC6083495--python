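"""Core genomic domain types and coordinate conventions.

All coordinates throughout the package are 0-based half-open (BED
convention). GTF input (1-based closed) is converted on read. The
"3' end" of a locus is its ``end`` coordinate on the + strand and its
``start`` coordinate on the - strand; a readthrough region extends 3'
of that point, i.e. rightwards for + genes and leftwards for - genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "GeneLocus",
    "AlignmentRecord",
    "DoGParams",
    "DoGRecord",
    "three_prime_end",
    "downstream_interval",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneLocus:
    """One gene's most-inclusive genomic extent.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open interval.
    strand : str
        ``"+"`` or ``"-"``.
    gene_id : str
        Primary gene identifier.
    source_count : int
        Number of annotation sources (or merged genes) contributing.
    aliases : tuple of str
        Identifiers of other genes merged into this locus.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    source_count: int = 1
    aliases: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid locus interval [{self.start}, {self.end}) for {self.gene_id!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read (or mate) reduced to aligned blocks.

    ``blocks`` are the splice-aware aligned segments (half-open, sorted,
    non-overlapping); skip (N) operations contribute no block.
    ``strand`` is the *effective transcription strand* after protocol
    normalization; ``strand_informative`` is False for unstranded
    libraries, where the mapped strand carries no protocol meaning.
    """

    chrom: str
    blocks: Tuple[Tuple[int, int], ...]
    strand: str
    is_paired: bool = False
    mate_index: Optional[int] = None  # 1, 2 or None for single-end
    strand_informative: bool = True
    query_name: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("blocks must be non-empty")
        prev_end = None
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"empty block ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = e
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def reference_start(self) -> int:
        return self.blocks[0][0]

    @property
    def reference_end(self) -> int:
        return self.blocks[-1][1]


@dataclass(frozen=True)
class DoGParams:
    """Tuning parameters for readthrough discovery.

    ``min_dog_len`` / ``min_dog_cov`` are the minimal initial length and
    minimal coverage-breadth fraction a candidate must satisfy
    (defaults 4000 bp and 0.60). ``window_len`` / ``window_step``
    control the overlapping elongation windows (defaults 200/100 bp,
    i.e. 50% overlap); endpoints are resolved to ~``window_step``.
    """

    min_dog_len: int = 4000
    min_dog_cov: float = 0.60
    window_len: int = 200
    window_step: int = 100

    def __post_init__(self) -> None:
        if self.min_dog_len <= 0:
            raise ValueError("min_dog_len must be positive")
        if not (0 < self.min_dog_cov <= 1):
            raise ValueError("min_dog_cov must be in (0, 1]")
        if not (0 < self.window_step <= self.window_len <= self.min_dog_len):
            raise ValueError(
                "require 0 < window_step <= window_len <= min_dog_len, got "
                f"step={self.window_step}, window={self.window_len}, "
                f"min_dog_len={self.min_dog_len}"
            )


@dataclass(frozen=True)
class DoGRecord:
    """A called readthrough region anchored at a gene's 3' end."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid DoG interval [{self.start}, {self.end}) for {self.gene_id!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def three_prime_end(locus: GeneLocus) -> int:
    """Coordinate of the locus 3' end (``end`` on +, ``start`` on -)."""
    return locus.end if locus.strand == "+" else locus.start


def downstream_interval(
    locus: GeneLocus, length: int, chrom_len: int
) -> Tuple[int, int]:
    """Half-open interval of ``length`` bp immediately 3' of the locus.

    Clipped silently at chromosome boundaries; the returned interval may
    therefore be shorter than requested (possibly empty at a boundary).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if locus.end > chrom_len:
        raise ValueError(
            f"locus {locus.gene_id!r} extends beyond chromosome length {chrom_len}"
        )
    if locus.strand == "+":
        return locus.end, min(locus.end + length, chrom_len)
    return max(locus.start - length, 0), locus.start
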