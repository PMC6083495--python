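"""Build the global, most-inclusive gene-loci annotation.

Gene boundaries are made as inclusive as possible: within each
annotation source a gene's locus spans [min start, max end] over all
its features; across sources, loci are unified. Same-strand loci that
overlap by at least 1 bp are merged into a single locus (read density
inside another gene cannot be attributed to readthrough unambiguously),
named after the longest contributor with the rest kept as aliases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import formats_io
from .genomic_model import GeneLocus, three_prime_end

logger = logging.getLogger(__name__)

__all__ = ["LociAnnotation", "build_loci", "nearest_downstream_neighbor"]


@dataclass
class LociAnnotation:
    """Sorted gene loci with per-chromosome indices for neighbor queries."""

    loci: List[GeneLocus]
    _by_chrom: Dict[str, np.ndarray] = field(init=False, repr=False)
    _starts: np.ndarray = field(init=False, repr=False)
    _ends: np.ndarray = field(init=False, repr=False)
    _strands: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.start, l.end, l.strand))
        self._starts = np.array([l.start for l in self.loci], dtype=np.int64)
        self._ends = np.array([l.end for l in self.loci], dtype=np.int64)
        self._strands = np.array([l.strand for l in self.loci])
        self._by_chrom = {}
        for i, locus in enumerate(self.loci):
            self._by_chrom.setdefault(locus.chrom, []).append(i)
        self._by_chrom = {c: np.array(ix, dtype=np.intp) for c, ix in self._by_chrom.items()}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.array([], dtype=np.intp))

    @classmethod
    def from_bed(cls, path: Union[str, Path]) -> "LociAnnotation":
        return cls(formats_io.read_bed(path, cls=GeneLocus))

    def to_bed(self, path: Union[str, Path]) -> None:
        formats_io.write_bed(self.loci, path)

    def nearest_downstream_neighbor(
        self, locus: GeneLocus, stranded: bool = True
    ) -> Optional[int]:
        """Boundary coordinate of the nearest locus lying 3' of ``locus``.

        For a + query this is the ``start`` of the nearest other locus
        whose extent reaches past the query's 3' end; for a - query the
        ``end`` of the nearest locus reaching below it. Restricted to
        same-strand loci when ``stranded``. ``None`` when no such
        neighbor exists on the chromosome.
        """
        idx = self.chrom_indices(locus.chrom)
        if idx.size == 0:
            return None
        starts = self._starts[idx]
        ends = self._ends[idx]
        strands = self._strands[idx]
        q3p = three_prime_end(locus)
        not_self = ~(
            (starts == locus.start)
            & (ends == locus.end)
            & (strands == locus.strand)
        )
        mask = not_self
        if stranded:
            mask = mask & (strands == locus.strand)
        if locus.strand == "+":
            mask = mask & (ends > q3p)
            if not mask.any():
                return None
            dist = np.maximum(starts - q3p, 0)
            dist = np.where(mask, dist, np.iinfo(np.int64).max)
            best = int(np.argmin(dist))
            # deterministic tie-break: smallest boundary coordinate
            ties = np.flatnonzero(dist == dist[best])
            return int(starts[ties].min())
        mask = mask & (starts < q3p)
        if not mask.any():
            return None
        dist = np.maximum(q3p - ends, 0)
        dist = np.where(mask, dist, np.iinfo(np.int64).max)
        best = int(np.argmin(dist))
        ties = np.flatnonzero(dist == dist[best])
        return int(ends[ties].max())


def nearest_downstream_neighbor(
    loci: LociAnnotation, locus: GeneLocus, stranded: bool = True
) -> Optional[int]:
    """Module-level convenience wrapper."""
    return loci.nearest_downstream_neighbor(locus, stranded=stranded)


def _per_gene_extents(
    sources: Sequence[Union[str, Path]]
) -> Dict[Tuple[str, str, str], Tuple[int, int, set]]:
    """(chrom, strand, gene_id) → (min start, max end, contributing sources)."""
    extents: Dict[Tuple[str, str, str], Tuple[int, int, set]] = {}
    for si, source in enumerate(sources):
        for rec in formats_io.read_gtf(source):
            key = (rec.chrom, rec.strand, rec.gene_id)
            if key in extents:
                s, e, srcs = extents[key]
                extents[key] = (min(s, rec.start), max(e, rec.end), srcs | {si})
            else:
                extents[key] = (rec.start, rec.end, {si})
    return extents


def build_loci(sources: Sequence[Union[str, Path]]) -> LociAnnotation:
    """Construct the unified loci annotation from one or more GTF files.

    Merging across (and within) sources is geometric: same-chromosome,
    same-strand extents overlapping by >= 1 bp collapse into one locus
    spanning their union. The merged locus takes the gene_id of its
    longest contributor; other contributors become aliases.
    """
    if not sources:
        raise ValueError("at least one annotation source is required")
    extents = _per_gene_extents(sources)
    if not extents:
        raise ValueError("no usable annotation records found in any source")

    # group per (chrom, strand), sweep to merge overlapping extents
    grouped: Dict[Tuple[str, str], List[Tuple[int, int, str, int]]] = {}
    for (chrom, strand, gene_id), (start, end, srcs) in extents.items():
        grouped.setdefault((chrom, strand), []).append((start, end, gene_id, len(srcs)))

    loci: List[GeneLocus] = []
    for (chrom, strand), items in grouped.items():
        items.sort(key=lambda t: (t[0], t[1], t[2]))
        cluster: List[Tuple[int, int, str, int]] = []
        cluster_end = -1
        for item in items:
            if cluster and item[0] < cluster_end:  # >= 1 bp overlap
                cluster.append(item)
                cluster_end = max(cluster_end, item[1])
            else:
                if cluster:
                    loci.append(_finalize_cluster(chrom, strand, cluster))
                cluster = [item]
                cluster_end = item[1]
        if cluster:
            loci.append(_finalize_cluster(chrom, strand, cluster))
    return LociAnnotation(loci)


def _finalize_cluster(
    chrom: str, strand: str, cluster: List[Tuple[int, int, str, int]]
) -> GeneLocus:
    start = min(s for s, _, _, _ in cluster)
    end = max(e for _, e, _, _ in cluster)
    # longest contributor names the locus; ties resolved lexicographically
    primary = max(cluster, key=lambda t: (t[1] - t[0], t[2]))
    aliases = tuple(sorted(g for _, _, g, _ in cluster if g != primary[2]))
    if aliases:
        logger.info(
            "merged %d overlapping genes on %s%s into locus %r (aliases: %s)",
            len(cluster), chrom, strand, primary[2], ", ".join(aliases),
        )
    source_count = max(n for _, _, _, n in cluster)
    return GeneLocus(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        gene_id=primary[2],
        source_count=source_count,
        aliases=aliases,
    )
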