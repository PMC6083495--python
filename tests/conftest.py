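import logging

import numpy as np
import pytest

from dogscan.genomic_model import DoGParams
from dogscan.loci_builder import build_loci
from dogscan.preprocess import infer_library_type, normalize_strand
from dogscan.synthetic_fixtures import FixtureConfig, generate_fixture
from dogscan import formats_io

logging.getLogger("dogscan").setLevel(logging.ERROR)
logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture
def default_params():
    return DoGParams()


@pytest.fixture
def simple_fixture(tmp_path):
    """Three + strand genes, one with an 8 kb fully covered readthrough."""
    config = FixtureConfig(
        n_genes=3, readthrough_len=[8000, 0, 0], expression_depth=10.0,
        noise_rate=0.1, seed=7,
    )
    return generate_fixture(config, tmp_path / "fx")


def load_normalized(fixture):
    """Read a fixture's alignments back and normalize read strands with
    the library type inferred from its own loci."""
    loci = build_loci([fixture.gtf_path])
    raw, total = formats_io.read_alignments(fixture.alignment_path)
    spec = infer_library_type(raw, loci)
    records = [normalize_strand(r, spec) for r in raw]
    return loci, spec, records, total


def random_fixture_config(rng: np.random.Generator) -> FixtureConfig:
    """A randomized small-genome config (<= 100 kb, <= 20 genes) that
    stresses geometry, strand, breadth and window interactions."""
    n_genes = int(rng.integers(2, 9))
    gene_len = int(rng.integers(3, 9)) * 100
    gap = int(rng.integers(40, 90)) * 100
    rt_lens = [
        int(rng.integers(0, gap // 100)) * 100 if rng.random() < 0.6 else 0
        for _ in range(n_genes)
    ]
    breadths = [float(rng.choice([0.4, 0.55, 0.6, 0.7, 0.85, 1.0])) for _ in range(n_genes)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_genes)]
    return FixtureConfig(
        n_genes=n_genes,
        gene_len=gene_len,
        intergenic_gap=gap,
        strands=strands,
        expression_depth=float(rng.integers(3, 12)),
        readthrough_len=rt_lens,
        readthrough_breadth=breadths,
        noise_rate=float(rng.choice([0.0, 0.1, 0.5])),
        protocol=str(rng.choice(["forward", "reverse", "unstranded"])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def random_small_params(rng: np.random.Generator) -> DoGParams:
    step = int(rng.choice([50, 100, 150]))
    win = step * int(rng.choice([1, 2, 3]))
    return DoGParams(
        min_dog_len=int(rng.choice([1000, 2000, 3000])),
        min_dog_cov=float(rng.choice([0.5, 0.6, 0.75])),
        window_len=win,
        window_step=step,
    )
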