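import numpy as np
import pytest

from meiochrom.cli import miniature_config
from meiochrom.simulate import simulate_annotation, simulate_chipseq, simulate_rnaseq
from meiochrom.intervals import GenomeModel, GenomicInterval


@pytest.fixture(scope="session")
def mini_config():
    return miniature_config(seed=7)


@pytest.fixture(scope="session")
def mini_ann(mini_config):
    return simulate_annotation(mini_config)


@pytest.fixture(scope="session")
def mini_rnaseq(mini_config, mini_ann):
    """(reads_by_sample, truth CountTable) for the miniature study design."""
    return simulate_rnaseq(mini_config, mini_ann)


@pytest.fixture(scope="session")
def mini_chip(mini_config, mini_ann):
    return simulate_chipseq(mini_config, mini_ann, "meiotic")


@pytest.fixture
def toy_genome():
    return GenomeModel(
        [("chr1", 100_000), ("chr2", 60_000), ("chrX", 40_000)], ["chrX"]
    )


def random_intervals(rng, genome, n, with_unstranded=False):
    strands = ["+", "-", "."] if with_unstranded else ["+", "-"]
    out = []
    for i in range(n):
        chrom, length = list(genome)[rng.integers(0, len(genome))]
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(length, start + 5000) + 1))
        out.append(
            GenomicInterval(
                chrom, start, end, strands[rng.integers(0, len(strands))], f"iv{i}"
            )
        )
    return out
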