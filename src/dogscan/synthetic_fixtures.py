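"""Synthetic annotation + alignment fixtures with planted readthrough.

The generator lays out a multi-gene genome with configurable intergenic
gaps, expresses each gene at a chosen depth, and plants readthrough of
known length and coverage breadth downstream of selected genes, so
every pipeline stage can be exercised against a known truth without
external data.

Coverage breadth downstream of a gene is controlled per 100-bp cell:
in each cell of the planted readthrough interval a contiguous
sub-interval of ``round(breadth * 100)`` bases receives reads and the
rest receives none. Every discovery window therefore sees a breadth
equal to the configured value (up to 1% quantization), which makes a
planted region's callability under given discovery parameters
deterministic. Reads start uniformly across gene bodies; background
noise reads start uniformly across the chromosome.

What this emulates: the depth-, breadth- and geometry-dependence of
readthrough calling. What it does not: sequencing errors, GC bias,
fragment-length variation, isoform structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from . import formats_io
from .genomic_model import DoGParams, DoGRecord, GeneLocus, three_prime_end
from .preprocess import downsample_file

logger = logging.getLogger(__name__)

__all__ = ["FixtureConfig", "GeneTruth", "TruthSet", "Fixture", "generate_fixture", "depth_series"]

BREADTH_CELL = 100  # bp; granularity of planted-coverage control


def _broadcast(value, n: int, name: str) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or length {n}, got {len(value)}")
    return value


@dataclass
class FixtureConfig:
    """Genome layout and read-generation parameters.

    Depth is mean per-base read depth over expressed regions;
    ``readthrough_len`` of 0 plants no readthrough for that gene;
    ``readthrough_breadth`` is the fraction of downstream bases covered.
    ``strands`` is ``"plus"``, ``"minus"``, ``"alternate"`` or an
    explicit per-gene sequence. ``noise_rate`` is background reads per
    kb of chromosome. The seed is mandatory: identical config + seed
    reproduce the fixture byte for byte.
    """

    n_genes: int = 3
    gene_len: int = 2000
    intergenic_gap: int = 50_000
    n_chroms: int = 1
    chrom_len: Optional[int] = None
    strands: Union[str, Sequence[str]] = "plus"
    expression_depth: Union[float, Sequence[float]] = 10.0
    readthrough_len: Union[int, Sequence[int]] = 0
    readthrough_breadth: Union[float, Sequence[float]] = 1.0
    read_len: int = 100
    layout: str = "single"
    protocol: str = "forward"
    noise_rate: float = 0.0
    seed: int = 0
    allow_collisions: bool = False

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"invalid layout {self.layout!r}")
        if self.protocol not in ("forward", "reverse", "unstranded"):
            raise ValueError(f"invalid protocol {self.protocol!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        n = self.n_genes
        self.depths = [float(d) for d in _broadcast(self.expression_depth, n, "expression_depth")]
        self.rt_lens = [int(l) for l in _broadcast(self.readthrough_len, n, "readthrough_len")]
        self.rt_breadths = [
            float(b) for b in _broadcast(self.readthrough_breadth, n, "readthrough_breadth")
        ]
        if isinstance(self.strands, str):
            if self.strands == "plus":
                self.strand_list = ["+"] * n
            elif self.strands == "minus":
                self.strand_list = ["-"] * n
            elif self.strands == "alternate":
                self.strand_list = ["+" if i % 2 == 0 else "-" for i in range(n)]
            else:
                raise ValueError(f"unknown strand rule {self.strands!r}")
        else:
            self.strand_list = list(self.strands)
            if len(self.strand_list) != n:
                raise ValueError("explicit strands must match n_genes")
        max_rt = max(self.rt_lens, default=0)
        if not self.allow_collisions and self.intergenic_gap <= max_rt:
            raise ValueError(
                f"intergenic_gap ({self.intergenic_gap}) must exceed the longest "
                f"planted readthrough ({max_rt}); set allow_collisions=True to "
                "configure a collision deliberately"
            )
        needed = self.n_genes * (self.gene_len + self.intergenic_gap) + self.intergenic_gap
        if self.chrom_len is None:
            self.chrom_len = needed
        elif self.chrom_len < needed:
            raise ValueError(
                f"chrom_len {self.chrom_len} cannot fit {self.n_genes} genes of "
                f"{self.gene_len} bp with {self.intergenic_gap} bp gaps (need {needed})"
            )

    def gene_layout(self) -> List[GeneLocus]:
        loci = []
        for ci in range(self.n_chroms):
            chrom = f"chr{ci + 1}"
            for gi in range(self.n_genes):
                start = self.intergenic_gap + gi * (self.gene_len + self.intergenic_gap)
                loci.append(
                    GeneLocus(
                        chrom=chrom,
                        start=start,
                        end=start + self.gene_len,
                        strand=self.strand_list[gi],
                        gene_id=f"G{ci + 1:02d}_{gi + 1:03d}",
                    )
                )
        return loci


@dataclass(frozen=True)
class GeneTruth:
    """Planted ground truth for one gene."""

    locus: GeneLocus
    depth: float
    readthrough: Optional[Tuple[int, int]]  # planted downstream interval
    breadth: float
    room: int  # distance from 3' end to the nearest downstream gene / boundary

    @property
    def readthrough_len(self) -> int:
        return 0 if self.readthrough is None else self.readthrough[1] - self.readthrough[0]

    def quantized_breadth(self) -> float:
        return round(self.breadth * BREADTH_CELL) / BREADTH_CELL

    def expected_callable(self, params: DoGParams) -> bool:
        """Whether the planted signal passes the initial-interval test.

        The initial interval's breadth is the planted (quantized)
        breadth over the readthrough portion and 0 beyond it.
        """
        if self.room < params.min_dog_len:
            return False
        init_cov = (
            self.quantized_breadth()
            * min(self.readthrough_len, params.min_dog_len)
            / params.min_dog_len
        )
        return init_cov >= params.min_dog_cov

    def expected_record(self, params: DoGParams) -> Optional[DoGRecord]:
        if not self.expected_callable(params) or self.readthrough is None:
            return None
        locus = self.locus
        q3p = three_prime_end(locus)
        if locus.strand == "+":
            end = max(self.readthrough[1], q3p + params.min_dog_len)
            return DoGRecord(locus.chrom, q3p, end, "+", locus.gene_id)
        start = min(self.readthrough[0], q3p - params.min_dog_len)
        return DoGRecord(locus.chrom, start, q3p, "-", locus.gene_id)


@dataclass
class TruthSet:
    genes: List[GeneTruth]

    def expected_dogs(self, params: DoGParams) -> List[DoGRecord]:
        out = [t.expected_record(params) for t in self.genes]
        return [r for r in out if r is not None]

    def to_bed(self, path: Union[str, Path]) -> None:
        records = [
            DoGRecord(t.locus.chrom, t.readthrough[0], t.readthrough[1],
                      t.locus.strand, t.locus.gene_id)
            for t in self.genes
            if t.readthrough is not None
        ]
        formats_io.write_bed(records, path)


@dataclass
class Fixture:
    gtf_path: Path
    alignment_path: Path
    truth: TruthSet
    chrom_lengths: Dict[str, int]
    config: FixtureConfig


class _ReadEmitter:
    """Accumulates simulated reads and writes a coordinate-sorted SAM."""

    def __init__(self, config: FixtureConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.reads: List[Tuple[str, int, int, str, Optional[int], str, int, int]] = []
        self._n = 0

    def _mapped_strand(self, transcript_strand: str, mate_index: Optional[int]) -> str:
        proto = self.config.protocol
        if proto == "unstranded":
            base = "+" if self.rng.integers(2) == 0 else "-"
        elif proto == "forward":
            base = transcript_strand
        else:
            base = "-" if transcript_strand == "+" else "+"
        if mate_index == 2:
            return "-" if base == "+" else "+"
        return base

    def emit(self, chrom: str, start: int, length: int, transcript_strand: str) -> None:
        """One sequenced fragment: a single read, or a mate pair covering
        the fragment's two ends."""
        self._n += 1
        name = f"sim{self._n:07d}"
        if self.config.layout == "single":
            strand = self._mapped_strand(transcript_strand, None)
            self.reads.append((chrom, start, length, strand, None, name, start, length))
        else:
            half = max(1, length // 2)
            m1 = self._mapped_strand(transcript_strand, 1)
            m2 = "-" if m1 == "+" else "+"
            p1, l1 = start, half
            p2, l2 = start + length - half, half
            self.reads.append((chrom, p1, l1, m1, 1, name, p2, length))
            self.reads.append((chrom, p2, l2, m2, 2, name, p1, -length))

    def write_sam(self, path: Union[str, Path], chrom_lengths: Dict[str, int]) -> None:
        chroms = sorted(chrom_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
        }
        tid = {c: i for i, c in enumerate(chroms)}
        ordered = sorted(self.reads, key=lambda r: (tid[r[0]], r[1], r[5], r[4] or 0))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for chrom, start, length, strand, mate, name, mpos, tlen in ordered:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = name
                seg.reference_id = tid[chrom]
                seg.reference_start = start
                seg.mapping_quality = 60
                seg.cigarstring = f"{length}M"
                seg.query_sequence = "A" * length
                flag = 0
                if strand == "-":
                    flag |= 0x10
                if mate is not None:
                    flag |= 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
                    mate_strand_rev = strand == "+"  # mates map to opposite strands
                    if mate_strand_rev:
                        flag |= 0x20
                    seg.next_reference_id = tid[chrom]
                    seg.next_reference_start = mpos
                    seg.template_length = tlen
                seg.flag = flag
                out.write(seg)


def _write_gtf(loci: Sequence[GeneLocus], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            attrs = f'gene_id "{locus.gene_id}"; transcript_id "{locus.gene_id}.t1";'
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{locus.chrom}\tsim\t{feature}\t{locus.start + 1}\t{locus.end}"
                    f"\t.\t{locus.strand}\t.\t{attrs}\n"
                )


def generate_fixture(config: FixtureConfig, out_dir: Union[str, Path]) -> Fixture:
    """Write GTF + coordinate-sorted SAM + truth BED for one fixture."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    loci = config.gene_layout()
    chrom_lengths = {f"chr{i + 1}": int(config.chrom_len) for i in range(config.n_chroms)}
    emitter = _ReadEmitter(config, rng)
    truths: List[GeneTruth] = []

    per_chrom: Dict[str, List[GeneLocus]] = {}
    for locus in loci:
        per_chrom.setdefault(locus.chrom, []).append(locus)

    for chrom, chrom_loci in per_chrom.items():
        for gi, locus in enumerate(chrom_loci):
            depth = config.depths[gi]
            rt_len = config.rt_lens[gi]
            breadth = config.rt_breadths[gi]
            # gene-body reads: uniform fragment starts
            frag = config.read_len if config.layout == "single" else min(
                2 * config.read_len + 50, locus.length
            )
            n_body = int(round(depth * locus.length / frag))
            if config.layout == "paired":
                # each fragment yields two mates of frag/2 covered bases
                n_body = int(round(depth * locus.length / frag))
            for _ in range(n_body):
                start = int(rng.integers(locus.start, max(locus.start + 1, locus.end - frag + 1)))
                emitter.emit(chrom, start, min(frag, locus.end - start), locus.strand)

            q3p = three_prime_end(locus)
            rt_interval: Optional[Tuple[int, int]] = None
            if rt_len > 0 and depth > 0:
                if locus.strand == "+":
                    rt_interval = (q3p, min(q3p + rt_len, config.chrom_len))
                else:
                    rt_interval = (max(q3p - rt_len, 0), q3p)
                _plant_readthrough(emitter, rng, chrom, rt_interval, breadth, depth,
                                   locus.strand, config)
            # downstream room to next gene boundary (or chromosome edge)
            if locus.strand == "+":
                downstream = [l.start for l in chrom_loci if l.start >= locus.end]
                limit = min(downstream) if downstream else config.chrom_len
                room = limit - q3p
            else:
                upstream = [l.end for l in chrom_loci if l.end <= locus.start]
                limit = max(upstream) if upstream else 0
                room = q3p - limit
            truths.append(
                GeneTruth(locus=locus, depth=depth, readthrough=rt_interval,
                          breadth=breadth, room=room)
            )

    # background noise: uniform starts across each chromosome
    for chrom, clen in chrom_lengths.items():
        n_noise = int(round(config.noise_rate * clen / 1000))
        for _ in range(n_noise):
            start = int(rng.integers(0, clen - config.read_len))
            strand = "+" if rng.integers(2) == 0 else "-"
            emitter.emit(chrom, start, config.read_len, strand)

    gtf_path = out_dir / "annotation.gtf"
    sam_path = out_dir / "reads.sam"
    _write_gtf(loci, gtf_path)
    emitter.write_sam(sam_path, chrom_lengths)
    truth = TruthSet(genes=truths)
    truth.to_bed(out_dir / "truth.bed")
    logger.info(
        "fixture: %d genes, %d reads, %d planted readthrough regions",
        len(loci), len(emitter.reads), sum(t.readthrough is not None for t in truths),
    )
    return Fixture(
        gtf_path=gtf_path, alignment_path=sam_path, truth=truth,
        chrom_lengths=chrom_lengths, config=config,
    )


def _plant_readthrough(
    emitter: _ReadEmitter,
    rng: np.random.Generator,
    chrom: str,
    interval: Tuple[int, int],
    breadth: float,
    depth: float,
    strand: str,
    config: FixtureConfig,
) -> None:
    """Plant coverage at exact breadth, cell by cell.

    Each 100-bp cell receives a contiguous covered sub-interval of
    round(breadth * 100) bases at a random offset, stacked to the
    requested depth; the remainder of the cell stays uncovered.
    """
    covered_len = int(round(breadth * BREADTH_CELL))
    if covered_len == 0:
        return
    n_copies = max(1, int(round(depth)))
    start, end = interval
    for cell_start in range(start, end, BREADTH_CELL):
        cell_end = min(cell_start + BREADTH_CELL, end)
        cell_len = cell_end - cell_start
        clen = min(covered_len, cell_len)
        offset = int(rng.integers(0, cell_len - clen + 1))
        sub_start = cell_start + offset
        for _ in range(n_copies):
            emitter.emit(chrom, sub_start, clen, strand)


def depth_series(
    fixture: Fixture,
    targets: Sequence[int],
    out_dir: Union[str, Path],
    seed: int = 1,
) -> List[Path]:
    """Downsample one fixture's alignments to each target depth (in
    mapped reads), mirroring a library-depth titration. Targets must be
    ascending."""
    if list(targets) != sorted(targets):
        raise ValueError("targets must be ascending")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair_atomic = fixture.config.layout == "paired"
    paths = []
    for target in targets:
        out = out_dir / f"depth_{target}.sam"
        downsample_file(fixture.alignment_path, out, int(target), seed,
                        pair_atomic=pair_atomic)
        paths.append(out)
    return paths
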