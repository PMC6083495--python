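# Methods

## The problem

When RNA polymerase II fails to terminate at a gene's canonical
termination site it continues transcribing into the downstream
intergenic region, producing a readthrough transcript — a DoG
(downstream-of-gene transcript). Readthrough is broadly induced by
cellular stress (osmotic, heat, oxidative, hypoxic) and viral
infection, but standard RNA-seq quantifiers only count reads against
existing annotations and never see it. dogscan detects and quantifies
DoGs directly from genome-mapped RNA-seq alignments.

## The procedure

**Loci annotation.** Each gene's locus is made as inclusive as
possible: within one GTF source a gene spans the min start / max end of
all its features; across sources, extents on the same chromosome and
strand that overlap by ≥ 1 bp are merged geometrically into one locus.
Merging is by overlap rather than by identifier because RefSeq, UCSC
and Ensembl use incompatible naming, and because read density inside
any annotated gene cannot be attributed to readthrough unambiguously —
so overlapping same-strand genes must act as a single genic mask. A
merged locus is named after its longest contributor; the other ids are
kept as aliases. All internal coordinates are 0-based half-open (BED
convention); GTF input is shifted on read.

**Preprocessing.** Library strandedness is inferred from concordance
between read strands and gene strands, using reads that overlap loci on
exactly one strand: with concordance fraction f over up to 200 000
usable alignments, the call is forward if f ≥ 0.8, reverse if
1 − f ≥ 0.8, unstranded otherwise (threshold and sample size
configurable; 0.8 is conservative enough that genuinely stranded
protocols, which show f near 0 or 1, are never missed, while anything
ambiguous degrades safely to unstranded behavior). Each record's
effective transcript strand is then derived from the protocol: under
the forward protocol the single read / mate-1 keeps its mapped strand
and mate-2 flips; under the reverse protocol the converse. Because
discovery relies on continuous-coverage criteria, the number of calls
depends on sequencing depth; all samples are therefore subsampled
without replacement to a common mapped-read count (by default the
minimum across the sample set) before any cross-sample comparison. The
sampling unit is the read pair for paired layouts, so a pair is never
split, and the seed is mandatory and recorded in the manifest — an
unseeded subsample would make every downstream DoG list irreproducible.

**Discovery.** Genic reads — any read with ≥ 1 bp aligned-block overlap
with a locus (same effective strand for stranded libraries, either
strand otherwise) — are removed first, so alternative isoforms, UTR
variation and annotated non-coding RNAs cannot masquerade as
readthrough. Coverage is *breadth*: the fraction of bases covered by at
least one aligned block, depth ≥ 1, with splice gaps contributing
nothing. A gene becomes a candidate when the `min_dog_len` bases
immediately 3′ of its locus end reach breadth ≥ `min_dog_cov`
(comparisons are inclusive). Candidates are elongated in overlapping
running windows of `window_len` advancing by `window_step`: each
passing window moves the DoG end to its downstream edge, and the scan
stops at the first failing window — interior sub-threshold stretches do
not restart elongation. DoG extent is capped by the nearest gene lying
3′ of the query's end (same strand when stranded, any strand when
unstranded, which makes unstranded calls conservative); genes whose
downstream room is below `min_dog_len` are discarded outright, and the
chromosome end acts as the degenerate neighbor. At most one DoG is
called per gene per sample, anchored exactly at the annotated 3′ end.

**Set operations.** Union and intersection of per-sample DoG sets are
keyed by gene id (every DoG is gene-anchored by construction). Extents
combine by the most-downstream rule — largest end for + genes, smallest
start for − genes — preserving the anchor coordinate; intersection uses
the same rule by default (`combine="min"` gives the minimal common
extent instead).

**Quantification.** DoG expression is RPKM:
`count / ((length/1000) · (total_mapped/1e6))`, where `count` is the
number of records (mates counted individually, matching the read-level
depth accounting of preprocessing) with ≥ 1 bp overlap with the DoG,
strand-matched for stranded libraries, and `total_mapped` is the mapped
read count of the downsampled sample — so RPKMs across samples share
the normalization that depth equalization created. The genic filter is
not reapplied here: a read overlapping both a gene and a DoG counts for
the DoG (an `exclude_genic` toggle reverses this).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_dog_len` | 4000 bp | minimal initial downstream length that must pass the coverage test |
| `min_dog_cov` | 0.60 | minimal coverage breadth, initial interval and every elongation window |
| `window_len` | 200 bp | elongation window length |
| `window_step` | 100 bp | elongation window advance (50 % overlap) |
| strand threshold | 0.80 | concordance needed to call a stranded protocol |
| downsample target | auto (min) | common mapped-read depth across samples |

The 4000 bp / 60 % defaults suit polyA-selected libraries. For
non-polyA-selected (often nuclear-enriched) data, where readthrough
signal is pervasive, stricter settings such as 4500 bp / 80 % are
appropriate. The window geometry is a resolution/robustness trade-off:
endpoints are quantized to ~`window_step`, and the 50 % overlap
prevents a single short coverage gap from ending elongation one window
early; both are configurable.

## Synthetic fixtures

The generator lays out evenly spaced genes (default 2 kb genes, 50 kb
gaps — wide enough that planted readthrough and the discovery minimum
never collide unless a collision is configured deliberately), expresses
each at a mean depth (default 10×) with uniform read starts, and plants
readthrough of known length downstream of chosen genes. Planted
coverage breadth is controlled per 100-bp cell: each cell receives a
contiguous covered sub-interval of `round(breadth·100)` bases at a
seeded random offset, stacked `round(depth)` reads deep. Every
discovery window therefore sees breadth equal to the configured value
(±1 % quantization), which makes the callability and expected endpoint
of each planted region *deterministic* — the truth object computes both
in closed form. Background noise reads start uniformly across the
chromosome.

This emulates what the method is sensitive to — coverage breadth,
downstream geometry, strand protocol, library depth (via seeded
downsampling of a fixture) — and deliberately omits sequencing error,
GC bias, fragment-length variation and isoform structure. Passing tests
therefore demonstrate algorithmic correctness and the depth/threshold
response of the caller, not robustness to alignment artifacts in real
data.

## Numerical and design choices

- Threshold comparisons are inclusive (≥) everywhere; "minimal
  coverage" reads naturally as a closed bound, and a convention must be
  fixed for exact-boundary fixtures.
- Coverage is breadth (covered-base fraction), not mean depth: the
  criterion is continuity of signal, and breadth is insensitive to a
  few high-depth spikes.
- Chromosome-boundary clipping is silent; a gene without room is
  discarded by the same rule as a neighbor-limited gene.
- The elongation scan never re-tests the initial interval piecewise,
  and stops at the first failing window; a trailing partial window is
  evaluated against the neighbor limit so full coverage up to a
  neighbor yields an exactly truncated DoG.
- Neighbor queries measure from the query's 3′ end to the nearest
  boundary of any locus extending 3′ of it, clamped at zero on overlap;
  ties resolve to the most restrictive boundary, deterministically.
- Downsampling permutes pair-atomic units under a seeded generator and
  fills any remainder with single-record units, so the target is met
  exactly or the sample errors out (e.g. an odd target on purely paired
  data).
- Degenerate inputs: empty alignment files yield zero DoGs; an
  annotation/alignment chromosome-naming mismatch ("1" vs "chr1") is an
  error with a rename hint rather than a silent zero-call run.
- Per-base boolean coverage arrays are held in memory per chromosome;
  this is exact and fast at fixture scale and adequate for typical
  mammalian chromosomes, but a sparse interval representation would be
  preferable for many-chromosome genomes processed simultaneously.

## Problem sizes used in the checks

The automated checks run on small genomes by design: randomized
fixtures of ≤ 20 genes on ≤ 100 kb chromosomes for oracle-equivalence
(100 genomes against an independent per-base, exhaustive-window
reimplementation), 50 seeded fixtures for planted-truth recovery
(readthrough 4–20 kb, breadth ≥ 0.75, depth ≥ 5×), 20 seeds × 4 depths
for the depth-response check, and a 2-condition × 2-replicate pipeline
run for end-to-end determinism. These sizes exercise every code path
while keeping the whole suite under a minute.

## Known limitations

- Flat loci: no isoform or 3′-UTR modeling; readthrough from an
  unannotated distal polyA site is indistinguishable from termination
  failure.
- A single gap longer than a window ends a DoG even if strong signal
  resumes beyond it; recovered signal downstream of a gap is never
  reattached.
- In unstranded mode, convergent-gene readthrough is truncated at the
  opposite-strand neighbor and antisense signal inflates coverage;
  calls are conservative but less specific.
- RPKM uses mate-level counts; fragment-level (pair-collapsed)
  quantification would differ by ~2× on paired data and is not offered.
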