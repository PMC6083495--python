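import numpy as np
import pytest

from _bruteforce import bf_discover
from conftest import load_normalized, random_fixture_config, random_small_params
from dogscan.discovery import (
    CoverageIndex,
    EligibleGene,
    coverage_fraction,
    detect_candidate,
    discover_dogs,
    elongate,
    eligible_genes,
    filter_genic_reads,
)
from dogscan.genomic_model import AlignmentRecord, DoGParams, GeneLocus
from dogscan.loci_builder import LociAnnotation, build_loci
from dogscan.preprocess import LibrarySpec
from dogscan.synthetic_fixtures import FixtureConfig, generate_fixture


def _rec(start, end, strand="+", chrom="chr1", informative=True, blocks=None):
    return AlignmentRecord(
        chrom=chrom, blocks=blocks or ((start, end),), strand=strand,
        strand_informative=informative,
    )


CHROM_LEN = {"chr1": 100_000}


# --- genic filtering -------------------------------------------------------

def test_filter_genic_reads_basic():
    loci = LociAnnotation([GeneLocus("chr1", 1000, 2000, "+", "G")])
    inside = _rec(1500, 1600)
    intergenic = _rec(5000, 5100)
    kept = list(filter_genic_reads([inside, intergenic], loci, stranded=True))
    assert kept == [intergenic]


def test_filter_genic_reads_strand_sensitivity():
    loci = LociAnnotation([GeneLocus("chr1", 1000, 2000, "+", "G")])
    antisense = _rec(1500, 1600, strand="-")
    assert list(filter_genic_reads([antisense], loci, stranded=True)) == [antisense]
    assert list(filter_genic_reads([antisense], loci, stranded=False)) == []


def test_filter_genic_reads_spliced_block_overlap():
    loci = LociAnnotation([GeneLocus("chr1", 1000, 2000, "+", "G")])
    # splice gap spans the locus: no block overlaps it
    spanning = _rec(0, 0, blocks=((500, 900), (2500, 2600)))
    # second block dips into the locus by 1 bp
    touching = _rec(0, 0, blocks=((500, 900), (1999, 2100)))
    kept = list(filter_genic_reads([spanning, touching], loci, stranded=True))
    assert kept == [spanning]


# --- coverage fraction -----------------------------------------------------

def test_coverage_fraction_examples():
    index = CoverageIndex(CHROM_LEN)
    assert coverage_fraction(index, "chr1", (0, 10)) == 0.0
    index.add(_rec(0, 5))
    assert coverage_fraction(index, "chr1", (0, 10), "+") == 0.5
    index.add(_rec(4, 10))
    assert coverage_fraction(index, "chr1", (0, 10), "+") == 1.0  # overlap not double-counted


def test_coverage_fraction_strand_separation():
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(0, 10, strand="-"))
    assert coverage_fraction(index, "chr1", (0, 10), "+") == 0.0
    assert coverage_fraction(index, "chr1", (0, 10), "-") == 1.0
    assert coverage_fraction(index, "chr1", (0, 10), "any") == 1.0


def test_non_informative_reads_visible_on_both_strands():
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(0, 10, strand="+", informative=False))
    assert coverage_fraction(index, "chr1", (0, 10), "any") == 1.0
    assert coverage_fraction(index, "chr1", (0, 10), "-") == 1.0


def test_coverage_fraction_splice_gaps_uncovered():
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(0, 0, blocks=((0, 4), (8, 10))))
    assert coverage_fraction(index, "chr1", (0, 10), "+") == pytest.approx(0.6)


# --- candidate detection ---------------------------------------------------

def _gene(start=1000, end=2000, strand="+", room=50_000):
    locus = GeneLocus("chr1", start, end, strand, "G")
    limit = end + room if strand == "+" else start - room
    return EligibleGene(locus=locus, room=room, limit=limit)


def _index_with_breadth(start, length, breadth, strand="+"):
    """Cover `breadth` of [start, start+length) in one leading run."""
    index = CoverageIndex(CHROM_LEN)
    covered = int(round(length * breadth))
    if covered:
        index.add(_rec(start, start + covered, strand=strand))
    return index


@pytest.mark.parametrize(
    "breadth,expected", [(0.70, True), (0.599, False), (0.60, True)]
)
def test_detect_candidate_threshold_inclusive(breadth, expected):
    params = DoGParams(min_dog_len=4000, min_dog_cov=0.60)
    gene = _gene()
    index = _index_with_breadth(2000, 4000, breadth)
    candidate = detect_candidate(gene, params, index)
    assert (candidate is not None) is expected
    if candidate:
        assert candidate == (2000, 6000)


def test_detect_candidate_minus_strand():
    params = DoGParams(min_dog_len=2000, min_dog_cov=0.60)
    locus = GeneLocus("chr1", 50_000, 52_000, "-", "G")
    gene = EligibleGene(locus=locus, room=40_000, limit=10_000)
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(48_000, 50_000, strand="-"))
    assert detect_candidate(gene, params, index) == (48_000, 50_000)


# --- elongation ------------------------------------------------------------

def test_elongate_continuous_coverage_to_endpoint():
    params = DoGParams(min_dog_len=4000, min_dog_cov=0.60, window_len=200, window_step=100)
    gene = _gene(room=48_000, end=2000)
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(2000, 11_000))  # 9 kb continuous coverage past the 3' end
    dog = elongate((2000, 6000), gene, params, index)
    assert abs(dog.end - 11_000) <= params.window_step
    assert dog.start == 2000


def test_elongate_no_signal_past_initial_interval():
    params = DoGParams()
    gene = _gene(room=48_000, end=2000)
    index = _index_with_breadth(2000, 4000, 1.0)
    dog = elongate((2000, 6000), gene, params, index)
    assert (dog.start, dog.end) == (2000, 6000)
    assert dog.length == params.min_dog_len


def test_elongate_truncates_at_neighbor_limit():
    params = DoGParams()
    locus = GeneLocus("chr1", 1000, 2000, "+", "G")
    gene = EligibleGene(locus=locus, room=6000, limit=8000)
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(2000, 20_000))  # coverage continues far past the limit
    dog = elongate((2000, 6000), gene, params, index)
    assert dog.end == 8000


def test_elongate_minus_strand_mirror():
    params = DoGParams(min_dog_len=4000, min_dog_cov=0.60)
    locus = GeneLocus("chr1", 50_000, 52_000, "-", "G")
    gene = EligibleGene(locus=locus, room=48_000, limit=2000)
    index = CoverageIndex(CHROM_LEN)
    index.add(_rec(41_000, 50_000, strand="-"))
    dog = elongate((46_000, 50_000), gene, params, index)
    assert abs(dog.start - 41_000) <= params.window_step
    assert dog.end == 50_000


# --- eligibility / discard rule -------------------------------------------

def test_eligible_genes_discards_close_neighbors():
    params = DoGParams(min_dog_len=4000)
    loci = LociAnnotation([
        GeneLocus("chr1", 1000, 2000, "+", "A"),
        GeneLocus("chr1", 5000, 6000, "+", "B"),  # 3 kb gap: A discarded
        GeneLocus("chr1", 60_000, 61_000, "+", "C"),
    ])
    eligible = eligible_genes(loci, CHROM_LEN, params, stranded=True)
    ids = {g.locus.gene_id for g in eligible}
    assert ids == {"B", "C"}


def test_eligible_genes_chromosome_boundary_is_degenerate_neighbor():
    params = DoGParams(min_dog_len=4000)
    loci = LociAnnotation([GeneLocus("chr1", 90_000, 98_000, "+", "A")])
    assert eligible_genes(loci, CHROM_LEN, params, stranded=True) == []
    loci2 = LociAnnotation([GeneLocus("chr1", 1000, 3000, "-", "B")])
    assert eligible_genes(loci2, CHROM_LEN, params, stranded=True) == []


# --- full discovery --------------------------------------------------------

def test_discover_recovers_planted_readthrough(simple_fixture, default_params):
    loci, spec, records, _ = load_normalized(simple_fixture)
    dogs = discover_dogs(
        simple_fixture.alignment_path, loci, default_params, spec
    )
    assert len(dogs) == 1
    (dog,) = dogs
    truth = simple_fixture.truth.genes[0]
    assert dog.gene_id == truth.locus.gene_id
    assert abs(dog.length - 8000) <= default_params.window_step


def test_discover_zero_dogs_when_neighbors_too_close(tmp_path, default_params):
    config = FixtureConfig(
        n_genes=4, intergenic_gap=3000, expression_depth=50.0, seed=1,
        readthrough_len=0,
    )
    fx = generate_fixture(config, tmp_path / "close")
    loci, spec, _, _ = load_normalized(fx)
    assert discover_dogs(fx.alignment_path, loci, default_params, spec) == []


def test_discover_empty_alignment_file(tmp_path, default_params):
    config = FixtureConfig(n_genes=2, expression_depth=0.0, noise_rate=0.0, seed=1)
    fx = generate_fixture(config, tmp_path / "empty")
    loci = build_loci([fx.gtf_path])
    spec = LibrarySpec("single", "forward")
    assert discover_dogs(fx.alignment_path, loci, default_params, spec) == []


def test_discover_chromosome_name_mismatch_error(simple_fixture, default_params):
    renamed = LociAnnotation([
        GeneLocus("1", l.start, l.end, l.strand, l.gene_id)
        for l in build_loci([simple_fixture.gtf_path])
    ])
    with pytest.raises(ValueError, match="chr1"):
        discover_dogs(
            simple_fixture.alignment_path, renamed, default_params,
            LibrarySpec("single", "forward"),
        )


def test_discover_monotone_in_coverage_threshold(tmp_path):
    """Raising min_dog_cov never increases the DoG count or any DoG's
    length."""
    config = FixtureConfig(
        n_genes=4, readthrough_len=[8000, 6000, 5000, 0],
        readthrough_breadth=[0.95, 0.7, 0.55, 1.0], noise_rate=0.5, seed=21,
    )
    fx = generate_fixture(config, tmp_path / "mono")
    loci, spec, _, _ = load_normalized(fx)
    prev_dogs = None
    for cov in (0.5, 0.6, 0.7, 0.8, 0.9):
        params = DoGParams(min_dog_cov=cov)
        dogs = {d.gene_id: d for d in discover_dogs(fx.alignment_path, loci, params, spec)}
        if prev_dogs is not None:
            assert len(dogs) <= len(prev_dogs)
            assert set(dogs) <= set(prev_dogs)
            for gene_id, dog in dogs.items():
                assert dog.length <= prev_dogs[gene_id].length
        prev_dogs = dogs


def test_no_dog_overlaps_same_strand_locus(tmp_path, default_params):
    rng = np.random.default_rng(77)
    for _ in range(5):
        config = random_fixture_config(rng)
        fx = generate_fixture(config, tmp_path / f"s{config.seed}")
        loci, spec, _, _ = load_normalized(fx)
        if not spec.stranded:
            spec = LibrarySpec(spec.layout, "forward", spec.concordance_fraction)
        for dog in discover_dogs(fx.alignment_path, loci, default_params, spec):
            for locus in loci:
                if locus.strand != dog.strand or locus.chrom != dog.chrom:
                    continue
                assert not (dog.start < locus.end and dog.end > locus.start), (
                    dog, locus,
                )


def test_discover_matches_bruteforce_oracle_small():
    """Vectorized discovery equals the per-base exhaustive oracle on a
    handful of randomized genomes (the acceptance suite scales this up)."""
    rng = np.random.default_rng(5)
    import tempfile, pathlib

    for _ in range(5):
        config = random_fixture_config(rng)
        with tempfile.TemporaryDirectory() as d:
            fx = generate_fixture(config, pathlib.Path(d))
            loci, spec, records, _ = load_normalized(fx)
            params = random_small_params(rng)
            got = discover_dogs(
                records, loci, params, spec, chrom_lengths=fx.chrom_lengths
            )
            want = bf_discover(
                records, list(loci), fx.chrom_lengths, params, spec.stranded
            )
            assert got == want
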