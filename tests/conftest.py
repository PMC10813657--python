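import numpy as np
import pytest

from difcir import EccDnaRecord, GeneModel, PipelineConfig, SimConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_genes():
    return [
        GeneModel("GeneA", "GeneA", "chr1", 0, 1000, "+"),
        GeneModel("GeneB", "GeneB", "chr1", 2000, 5000, "-"),
        GeneModel("GeneC", "GeneC", "chr2", 100, 600, "+"),
    ]


def make_record(chrom="chr1", start=100, end=500, sr=3, sample="s1"):
    return EccDnaRecord(sample, chrom, start, end, sr)


@pytest.fixture
def random_records():
    """Factory for random single-sample record sets (seeded)."""

    def build(seed, n=30, chroms=("chr1", "chr2"), span=2000, sample="s1"):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, span))
            length = int(rng.integers(1, 400))
            sr = int(rng.integers(1, 8))
            out.append(EccDnaRecord(sample, chrom, start, start + length, sr))
        return out

    return build


@pytest.fixture
def tiny_sim_config():
    """A fast synthetic cohort: small genome, few samples."""
    return SimConfig(
        n_chroms=2,
        genes_per_chrom=10,
        n_samples_per_group=(3, 3),
        background_rate=60.0,
        effect_genes=4,
        effect_multiplier=10.0,
        seed=11,
    )
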