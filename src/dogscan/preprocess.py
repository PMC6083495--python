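"""Sample preprocessing: library-type inference, per-read strand
normalization and seeded downsampling to a common depth.

Readthrough discovery relies on continuous-coverage criteria, so the
number of calls depends on sequencing depth. Before samples can be
compared, all alignment files are subsampled (without replacement,
pair-atomically for paired layouts) to a common number of mapped reads.
Strandedness is inferred directly from concordance between read strands
and the strands of unambiguously assignable gene loci.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam
from intervaltree import IntervalTree

from .formats_io import RawAlignment, aligned_blocks, read_alignments
from .genomic_model import AlignmentRecord
from .loci_builder import LociAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "SampleEntry",
    "SampleManifest",
    "infer_library_type",
    "normalize_strand",
    "downsample_file",
    "downsample",
    "preprocess_samples",
]

DEFAULT_STRAND_THRESHOLD = 0.8
DEFAULT_SAMPLE_SIZE = 200_000


@dataclass(frozen=True)
class LibrarySpec:
    """Inferred sequencing protocol.

    ``forward``: the single read / mate-1 maps on the transcript strand;
    ``reverse``: opposite; ``unstranded``: neither hypothesis reached
    the concordance threshold.
    """

    layout: str  # "single" | "paired"
    strandedness: str  # "forward" | "reverse" | "unstranded"
    concordance_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"invalid layout {self.layout!r}")
        if self.strandedness not in ("forward", "reverse", "unstranded"):
            raise ValueError(f"invalid strandedness {self.strandedness!r}")

    @property
    def stranded(self) -> bool:
        return self.strandedness != "unstranded"


def _loci_trees(loci: LociAnnotation) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for locus in loci:
        trees.setdefault((locus.chrom, locus.strand), IntervalTree()).addi(
            locus.start, locus.end
        )
    return trees


def _overlap_strands(
    trees: Dict[Tuple[str, str], IntervalTree],
    chrom: str,
    blocks: Sequence[Tuple[int, int]],
) -> set:
    hit = set()
    for strand in ("+", "-"):
        tree = trees.get((chrom, strand))
        if tree is None:
            continue
        for s, e in blocks:
            if tree.overlaps(s, e):
                hit.add(strand)
                break
    return hit


def infer_library_type(
    alignments: Iterable[RawAlignment],
    loci: LociAnnotation,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    threshold: float = DEFAULT_STRAND_THRESHOLD,
) -> LibrarySpec:
    """Infer layout and strandedness from the first ``sample_size``
    alignments that overlap exactly one locus strand.

    A read is consistent with the *forward* hypothesis when the single
    read / mate-1 maps on its gene's strand (mate-2 opposite). With
    concordance fraction ``f``, the call is forward if ``f >= threshold``,
    reverse if ``1 - f >= threshold``, unstranded otherwise.
    """
    if len(loci) == 0:
        raise ValueError("loci annotation is empty")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    trees = _loci_trees(loci)
    used = 0
    forward_votes = 0
    paired_votes = 0
    for rec in alignments:
        strands = _overlap_strands(trees, rec.chrom, rec.blocks)
        if len(strands) != 1:
            continue  # intergenic or ambiguous (both strands annotated)
        gene_strand = next(iter(strands))
        expect_same = rec.mate_index != 2  # single read or mate-1
        consistent = (rec.mapped_strand == gene_strand) == expect_same
        used += 1
        forward_votes += consistent
        paired_votes += rec.is_paired
        if used >= sample_size:
            break
    if used == 0:
        raise ValueError("no alignments overlap an unambiguous locus; cannot infer library type")
    if used < min(sample_size, 1000):
        logger.warning(
            "library-type inference used only %d usable alignments (requested %d)",
            used, sample_size,
        )
    f = forward_votes / used
    layout = "paired" if paired_votes * 2 > used else "single"
    if f >= threshold:
        strandedness = "forward"
    elif (1 - f) >= threshold:
        strandedness = "reverse"
    else:
        strandedness = "unstranded"
    return LibrarySpec(layout=layout, strandedness=strandedness, concordance_fraction=f)


_FLIP = {"+": "-", "-": "+"}


def normalize_strand(record: RawAlignment, spec: LibrarySpec) -> AlignmentRecord:
    """Map a raw alignment's mapped strand to the transcript strand.

    Forward protocol: single read / mate-1 keep the mapped strand,
    mate-2 is flipped. Reverse protocol: the converse. Unstranded: the
    mapped strand is kept but flagged non-informative.
    """
    strand = record.mapped_strand
    informative = True
    if spec.strandedness == "unstranded":
        informative = False
    else:
        is_mate2 = record.mate_index == 2
        flip = is_mate2 if spec.strandedness == "forward" else not is_mate2
        if flip:
            strand = _FLIP[strand]
    return AlignmentRecord(
        chrom=record.chrom,
        blocks=record.blocks,
        strand=strand,
        is_paired=record.is_paired,
        mate_index=record.mate_index,
        strand_informative=informative,
        query_name=record.query_name,
    )


# ---------------------------------------------------------------------------
# Downsampling


def _sampling_units(path: Union[str, Path], pair_atomic: bool) -> List[Tuple[str, int]]:
    """(unit key, record count) per sampling unit, in deterministic order.

    For paired layouts the unit is the read pair (keyed by query name);
    otherwise each primary mapped record is its own unit.
    """
    counts: Dict[str, int] = {}
    order: List[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for i, read in enumerate(af):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            key = read.query_name if pair_atomic else f"{read.query_name}/{i}"
            if key not in counts:
                counts[key] = 0
                order.append(key)
            counts[key] += 1
    return [(k, counts[k]) for k in sorted(order)]


def downsample_file(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    target: int,
    seed: int,
    pair_atomic: bool = True,
) -> int:
    """Subsample a SAM/BAM file to exactly ``target`` mapped reads.

    Sampling is without replacement and, for paired data, pair-atomic:
    both mates of a pair are kept or dropped together. The same seed and
    input always produce the same output. Returns the number of reads
    written.
    """
    units = _sampling_units(in_path, pair_atomic)
    total = sum(n for _, n in units)
    if target > total:
        raise ValueError(
            f"target {target} exceeds the {total} mapped reads of {in_path}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(units))
    chosen: set = set()
    kept = 0
    deferred: List[int] = []
    for idx in perm:
        key, n = units[idx]
        if kept + n <= target:
            chosen.add(key)
            kept += n
        else:
            deferred.append(idx)
    if kept < target:
        # fill the remainder with smaller (e.g. unpaired) units
        for idx in deferred:
            key, n = units[idx]
            if kept + n <= target:
                chosen.add(key)
                kept += n
            if kept == target:
                break
    if kept != target:
        raise ValueError(
            f"cannot reach exactly {target} reads of {in_path} with "
            f"pair-atomic sampling (closest achievable: {kept})"
        )
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    written = 0
    with pysam.AlignmentFile(str(in_path), check_sq=False) as src:
        with pysam.AlignmentFile(str(out_path), mode, template=src) as dst:
            for i, read in enumerate(src):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                key = read.query_name if pair_atomic else f"{read.query_name}/{i}"
                if key in chosen:
                    dst.write(read)
                    written += 1
    return written


@dataclass
class SampleEntry:
    """Manifest row for one preprocessed sample."""

    path: str
    total_mapped: int
    spec: LibrarySpec
    prep_path: str
    downsampled_path: Optional[str] = None
    downsample_target: Optional[int] = None
    downsample_seed: Optional[int] = None


@dataclass
class SampleManifest:
    samples: List[SampleEntry] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = [
            {**asdict(s), "spec": asdict(s.spec)} for s in self.samples
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        logger.info("wrote manifest for %d samples to %s", len(self.samples), path)


def downsample(
    manifest: SampleManifest,
    target: Union[int, str] = "auto",
    seed: int = 1,
) -> SampleManifest:
    """Downsample every sample in the manifest to a common depth.

    ``target="auto"`` equalizes to the minimum mapped-read count across
    samples; a numeric target must not exceed any sample's total.
    """
    if not manifest.samples:
        raise ValueError("empty manifest")
    if target == "auto":
        target = min(s.total_mapped for s in manifest.samples)
    target = int(target)
    for entry in manifest.samples:
        if target > entry.total_mapped:
            raise ValueError(
                f"target {target} exceeds total mapped reads "
                f"({entry.total_mapped}) of sample {entry.path}"
            )
    for entry in manifest.samples:
        prep = Path(entry.prep_path)
        suffix = ".bam" if prep.suffix == ".bam" else ".sam"
        out = prep.parent / (prep.name.replace(".prep", ".ds"))
        if out == prep:
            out = prep.parent / (prep.stem + ".ds" + suffix)
        pair_atomic = entry.spec.layout == "paired"
        downsample_file(prep, out, target, seed, pair_atomic=pair_atomic)
        entry.downsampled_path = str(out)
        entry.downsample_target = target
        entry.downsample_seed = seed
    return manifest


def _prep_one(
    path: Union[str, Path],
    loci: LociAnnotation,
    out_dir: Path,
    sample_size: int,
    threshold: float,
    name: Optional[str] = None,
) -> SampleEntry:
    records, total = read_alignments(path)
    spec = infer_library_type(records, loci, sample_size=sample_size, threshold=threshold)
    in_path = Path(path)
    suffix = ".bam" if in_path.suffix == ".bam" else ".sam"
    prep_path = out_dir / ((name or in_path.stem) + ".prep" + suffix)
    mode = "wb" if suffix == ".bam" else "w"
    kept = 0
    with pysam.AlignmentFile(str(in_path), check_sq=False) as src:
        with pysam.AlignmentFile(str(prep_path), mode, template=src) as dst:
            for read in src:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                dst.write(read)
                kept += 1
    logger.info(
        "%s: %s %s library (concordance %.3f), %d mapped reads",
        in_path.name, spec.layout, spec.strandedness, spec.concordance_fraction, kept,
    )
    return SampleEntry(
        path=str(in_path), total_mapped=kept, spec=spec, prep_path=str(prep_path)
    )


def preprocess_samples(
    paths: Sequence[Union[str, Path]],
    loci: LociAnnotation,
    out_dir: Union[str, Path],
    target: Union[int, str] = "auto",
    seed: int = 1,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    threshold: float = DEFAULT_STRAND_THRESHOLD,
    threads: int = 1,
    names: Optional[Sequence[str]] = None,
) -> SampleManifest:
    """Full preprocessing: infer library types, write filtered ``.prep``
    files and depth-equalized ``.ds`` files, return the manifest.

    ``names`` sets per-sample output basenames (distinct input files
    with identical stems are disambiguated automatically). Per-sample
    work may run in parallel (``threads``); outputs are independent of
    the thread count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if names is None:
        names = []
        seen: Dict[str, int] = {}
        for p in paths:
            base = Path(p).stem
            seen[base] = seen.get(base, 0) + 1
            names.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    elif len(names) != len(paths):
        raise ValueError("names must match paths")
    jobs = list(zip(paths, names))
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            entries = list(
                pool.map(
                    lambda job: _prep_one(job[0], loci, out_dir, sample_size,
                                          threshold, name=job[1]),
                    jobs,
                )
            )
    else:
        entries = [
            _prep_one(p, loci, out_dir, sample_size, threshold, name=n)
            for p, n in jobs
        ]
    manifest = SampleManifest(samples=entries)
    return downsample(manifest, target=target, seed=seed)
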