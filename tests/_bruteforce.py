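"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written with plain-python loops over
per-base boolean arrays and exhaustive scans, sharing no code with the
package's vectorized/indexed implementations.
"""

from typing import Dict, List, Optional, Sequence, Tuple

from dogscan.genomic_model import AlignmentRecord, DoGParams, DoGRecord, GeneLocus


def bf_coverage(
    records: Sequence[AlignmentRecord],
    chrom: str,
    chrom_len: int,
    strand: str,
) -> List[bool]:
    """Per-base boolean coverage for one chromosome and strand query."""
    cov = [False] * chrom_len
    for rec in records:
        if rec.chrom != chrom:
            continue
        if strand != "any" and rec.strand_informative and rec.strand != strand:
            continue
        for s, e in rec.blocks:
            for pos in range(max(s, 0), min(e, chrom_len)):
                cov[pos] = True
    return cov


def bf_nongenic(
    records: Sequence[AlignmentRecord],
    loci: Sequence[GeneLocus],
    stranded: bool,
) -> List[AlignmentRecord]:
    out = []
    for rec in records:
        genic = False
        for locus in loci:
            if locus.chrom != rec.chrom:
                continue
            if stranded and locus.strand != rec.strand:
                continue
            for s, e in rec.blocks:
                if s < locus.end and e > locus.start:
                    genic = True
                    break
            if genic:
                break
        if not genic:
            out.append(rec)
    return out


def bf_neighbor(
    loci: Sequence[GeneLocus], query: GeneLocus, stranded: bool
) -> Optional[int]:
    """Linear-scan nearest 3' neighbor boundary."""
    q3p = query.end if query.strand == "+" else query.start
    best = None
    best_dist = None
    for other in loci:
        if other.chrom != query.chrom:
            continue
        if (other.start, other.end, other.strand) == (query.start, query.end, query.strand):
            continue
        if stranded and other.strand != query.strand:
            continue
        if query.strand == "+":
            if other.end <= q3p:
                continue
            dist = max(0, other.start - q3p)
            pos = other.start
        else:
            if other.start >= q3p:
                continue
            dist = max(0, q3p - other.end)
            pos = other.end
        if best_dist is None or dist < best_dist:
            best, best_dist = pos, dist
        elif dist == best_dist:
            # match the package's deterministic tie-break
            best = min(best, pos) if query.strand == "+" else max(best, pos)
    return best


def _frac(cov: List[bool], start: int, end: int) -> float:
    return sum(cov[start:end]) / (end - start)


def bf_discover(
    records: Sequence[AlignmentRecord],
    loci: Sequence[GeneLocus],
    chrom_lengths: Dict[str, int],
    params: DoGParams,
    stranded: bool,
) -> List[DoGRecord]:
    """Exhaustive per-base reimplementation of DoG calling."""
    nongenic = bf_nongenic(records, loci, stranded)
    cov_cache: Dict[Tuple[str, str], List[bool]] = {}

    def coverage(chrom: str, strand: str) -> List[bool]:
        key = (chrom, strand)
        if key not in cov_cache:
            cov_cache[key] = bf_coverage(nongenic, chrom, chrom_lengths[chrom], strand)
        return cov_cache[key]

    dogs: List[DoGRecord] = []
    for locus in loci:
        if locus.chrom not in chrom_lengths:
            continue
        chrom_len = chrom_lengths[locus.chrom]
        q3p = locus.end if locus.strand == "+" else locus.start
        neighbor = bf_neighbor(loci, locus, stranded)
        if locus.strand == "+":
            limit = chrom_len if neighbor is None else min(neighbor, chrom_len)
            room = limit - q3p
        else:
            limit = 0 if neighbor is None else max(neighbor, 0)
            room = q3p - limit
        if room < params.min_dog_len:
            continue
        strand_q = locus.strand if stranded else "any"
        cov = coverage(locus.chrom, strand_q)
        L, threshold = params.min_dog_len, params.min_dog_cov
        win, step = params.window_len, params.window_step
        if locus.strand == "+":
            if _frac(cov, q3p, q3p + L) < threshold:
                continue
            end = q3p + L
            ws = end
            while True:
                we = ws + win
                if we > limit:
                    if limit > ws and _frac(cov, ws, limit) >= threshold:
                        end = limit
                    break
                if _frac(cov, ws, we) >= threshold:
                    end = we
                    ws += step
                else:
                    break
            dogs.append(DoGRecord(locus.chrom, q3p, min(end, limit), "+", locus.gene_id))
        else:
            if _frac(cov, q3p - L, q3p) < threshold:
                continue
            start = q3p - L
            we = start
            while True:
                ws = we - win
                if ws < limit:
                    if we > limit and _frac(cov, limit, we) >= threshold:
                        start = limit
                    break
                if _frac(cov, ws, we) >= threshold:
                    start = ws
                    we -= step
                else:
                    break
            dogs.append(DoGRecord(locus.chrom, max(start, limit), q3p, "-", locus.gene_id))
    dogs.sort(key=lambda d: (d.chrom, d.start, d.end))
    return dogs
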