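"""Counting: genes (union-mode), piRNA clusters (masked, opposite-strand),
repeat families, the RPM floor, and window coverage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meiochrom.alignio import AlignmentRecord
from meiochrom.intervals import (
    FeatureSet,
    GenomeModel,
    GenomicInterval,
    build_mask,
    make_windows,
)
from meiochrom.quantify import (
    CountTable,
    count_gene_sample,
    count_pirna_sample,
    count_repeat_sample,
    make_sample_sheet,
    rpm_filter,
    window_coverage,
)


@pytest.fixture
def genome():
    return GenomeModel([("chr1", 200_000)])


def read(chrom, start, end, strand, name="r", unique=True, blocks=None):
    return AlignmentRecord(name, chrom, blocks or ((start, end),), strand, unique)


class TestCountGenes:
    def test_read_inside_gene_opposite_strand(self, genome):
        genes = FeatureSet([GenomicInterval("chr1", 1_000, 2_000, "+", "g1", "gene")])
        counts, stats = count_gene_sample([read("chr1", 1_100, 1_150, "-")], genes)
        assert counts["g1"] == 1 and stats["assigned"] == 1

    def test_same_strand_read_not_counted_in_opposite_mode(self, genome):
        genes = FeatureSet([GenomicInterval("chr1", 1_000, 2_000, "+", "g1", "gene")])
        counts, stats = count_gene_sample([read("chr1", 1_100, 1_150, "+")], genes)
        assert counts["g1"] == 0 and stats["no_feature"] == 1

    def test_read_spanning_two_genes_is_ambiguous(self, genome):
        genes = FeatureSet(
            [
                GenomicInterval("chr1", 1_000, 2_000, "+", "g1", "gene"),
                GenomicInterval("chr1", 1_990, 3_000, "+", "g2", "gene"),
            ]
        )
        counts, stats = count_gene_sample([read("chr1", 1_980, 2_030, "-")], genes)
        assert counts.sum() == 0 and stats["ambiguous"] == 1

    def test_every_block_must_overlap(self, genome):
        genes = FeatureSet([GenomicInterval("chr1", 1_000, 2_000, "+", "g1", "gene")])
        r = read("chr1", 0, 0, "-", blocks=((1_900, 1_925), (2_500, 2_525)))
        counts, stats = count_gene_sample([r], genes)
        assert counts["g1"] == 0 and stats["no_feature"] == 1

    def test_conservation(self, genome):
        rng = np.random.default_rng(0)
        genes = FeatureSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 2_000, "+-"[i % 2], f"g{i}", "gene")
                for i, s in enumerate(range(0, 180_000, 20_000))
            ]
        )
        reads = [
            read("chr1", int(s), int(s) + 50, "+-"[int(rng.integers(0, 2))], f"r{i}")
            for i, s in enumerate(rng.integers(0, 190_000, size=500))
        ]
        counts, stats = count_gene_sample(reads, genes)
        assert stats["assigned"] + stats["ambiguous"] + stats["no_feature"] == stats["input"]
        assert counts.sum() == stats["assigned"]


class TestCountPirna:
    def test_three_rule_hand_trace(self, genome):
        """Split removal + opposite-strand genic masking (3 kb / 10 kb) +
        opposite-strand cluster assignment: hand-traced final count is 1."""
        genes = FeatureSet(
            [GenomicInterval("chr1", 1_000, 2_000, "+", "g1", "gene", "protein_coding")]
        )
        mask = build_mask(genes, genome)  # -> [0, 12000)+
        assert [(m.start, m.end) for m in mask] == [(0, 12_000)]
        clusters = FeatureSet(
            [GenomicInterval("chr1", 20_000, 30_000, "+", "piC1", "pirna_cluster")]
        )
        r1 = read("chr1", 1_500, 1_550, "-", "r1")  # masked out
        r2 = read("chr1", 25_000, 25_050, "-", "r2")  # counted
        r3 = read("chr1", 0, 0, "-", "r3", blocks=((25_000, 25_025), (25_125, 25_150)))
        counts, stats = count_pirna_sample([r1, r2, r3], clusters, mask)
        assert counts["piC1"] == 1
        assert stats["masked"] == 1 and stats["split"] == 1 and stats["assigned"] == 1

    def test_cluster_without_reads_is_zero(self, genome):
        clusters = FeatureSet(
            [GenomicInterval("chr1", 20_000, 30_000, "+", "piC1", "pirna_cluster")]
        )
        counts, _ = count_pirna_sample([], clusters, FeatureSet())
        assert counts["piC1"] == 0

    def test_distant_gene_masks_nothing(self, genome):
        """With the gene moved > 10 kb beyond the cluster, masked counting
        equals unmasked counting."""
        rng = np.random.default_rng(2)
        clusters = FeatureSet(
            [GenomicInterval("chr1", 20_000, 30_000, "+", "piC1", "pirna_cluster")]
        )
        far_gene = FeatureSet(
            [GenomicInterval("chr1", 41_000, 45_000, "+", "g1", "gene", "protein_coding")]
        )
        mask = build_mask(far_gene, genome)
        reads = [
            read("chr1", int(s), int(s) + 50, "-", f"r{i}")
            for i, s in enumerate(rng.integers(19_000, 31_000, size=200))
        ]
        masked, _ = count_pirna_sample(reads, clusters, mask)
        unmasked, _ = count_pirna_sample(reads, clusters, FeatureSet())
        assert masked.equals(unmasked)

    def test_sample_strand_convention(self, genome):
        # plus-strand cluster: only minus reads assigned
        clusters = FeatureSet(
            [GenomicInterval("chr1", 20_000, 30_000, "+", "piC1", "pirna_cluster")]
        )
        counts, _ = count_pirna_sample(
            [read("chr1", 25_000, 25_050, "+"), read("chr1", 25_000, 25_050, "-")],
            clusters,
            FeatureSet(),
        )
        assert counts["piC1"] == 1


class TestCountRepeats:
    def test_family_counts_sum_over_instances(self, genome):
        reps = FeatureSet(
            [
                GenomicInterval("chr1", 1_000, 1_500, "+", "F/i1", "repeat", "F"),
                GenomicInterval("chr1", 5_000, 5_500, "-", "F/i2", "repeat", "F"),
                GenomicInterval("chr1", 9_000, 9_500, "+", "F/i3", "repeat", "F"),
            ]
        )
        reads = (
            [read("chr1", 1_000 + 10 * i, 1_060 + 10 * i, "+", f"a{i}") for i in range(5)]
            + [read("chr1", 9_100 + i, 9_160 + i, "-", f"b{i}") for i in range(2)]
        )
        counts, stats = count_repeat_sample(reads, reps)
        assert counts["F"] == 7 and stats["assigned"] == 7

    def test_read_over_two_families_counted_in_both(self, genome):
        reps = FeatureSet(
            [
                GenomicInterval("chr1", 1_000, 1_500, "+", "A/i1", "repeat", "A"),
                GenomicInterval("chr1", 1_480, 2_000, "+", "B/i1", "repeat", "B"),
            ]
        )
        counts, stats = count_repeat_sample([read("chr1", 1_460, 1_510, "+")], reps)
        assert counts["A"] == 1 and counts["B"] == 1 and stats["multi_family"] == 1


class TestRpmFilter:
    def sheet(self, lib=10_000_000):
        return make_sample_sheet(
            [
                {"sample": "s1", "condition": "WT", "stage": "meiotic", "assay": "rnaseq", "library_size": lib},
                {"sample": "s2", "condition": "KO", "stage": "meiotic", "assay": "rnaseq", "library_size": lib},
            ]
        )

    def test_threshold_boundary(self):
        counts = pd.DataFrame({"s1": [40, 60], "s2": [40, 60]}, index=["low", "high"])
        table = CountTable(counts, self.sheet())
        kept, excluded = rpm_filter(table, floor=5.0)
        assert excluded == ["low"] and list(kept.counts.index) == ["high"]

    def test_any_sample_above_floor_keeps_family_by_default(self):
        counts = pd.DataFrame({"s1": [40], "s2": [60]}, index=["f"])
        kept, excluded = rpm_filter(CountTable(counts, self.sheet()), floor=5.0)
        assert excluded == []
        kept_any, excluded_any = rpm_filter(
            CountTable(counts, self.sheet()), floor=5.0, mode="any"
        )
        assert excluded_any == ["f"]

    def test_floor_zero_is_identity(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [1, 0]}, index=["a", "b"])
        kept, excluded = rpm_filter(CountTable(counts, self.sheet()), floor=0.0)
        assert excluded == [] and kept.counts.equals(counts)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [1]}, index=["a"])
        with pytest.raises(ValueError):
            rpm_filter(CountTable(counts, self.sheet(lib=0)))


class TestWindowCoverage:
    def test_normalization_arithmetic(self, genome):
        windows = make_windows(genome, 40_000)
        reads = [read("chr1", 100 + i, 150 + i, "+", f"r{i}") for i in range(50)]
        cov, stats = window_coverage(reads, windows, 20_000_000)
        assert cov.table["raw"].iloc[0] == 50
        assert cov.table["norm"].iloc[0] == pytest.approx(25.0)

    def test_five_prime_assignment_is_strand_aware(self, genome):
        windows = make_windows(genome, 40_000)
        # minus read straddling the window boundary: 5' base is its right end
        r = read("chr1", 39_990, 40_040, "-")
        cov, _ = window_coverage([r], windows, 1_000)
        assert cov.table.loc[cov.table["start"] == 40_000, "raw"].iloc[0] == 1

    def test_conservation(self, genome):
        rng = np.random.default_rng(8)
        windows = make_windows(genome, 40_000)
        reads = [
            read("chr1", int(s), int(s) + 50, "+", f"r{i}")
            for i, s in enumerate(rng.integers(0, 199_000, size=777))
        ]
        cov, stats = window_coverage(reads, windows, 1_000_000)
        assert cov.table["raw"].sum() == stats["assigned"] == 777

    def test_uniform_reads_poisson_per_window(self):
        genome = GenomeModel([("chr1", 4_000_000)])
        windows = make_windows(genome, 40_000)
        rng = np.random.default_rng(123)
        n = 20_000
        reads = [
            read("chr1", int(s), int(s) + 50, "+", f"r{i}")
            for i, s in enumerate(rng.integers(0, 3_999_000, size=n))
        ]
        cov, _ = window_coverage(reads, windows, n)
        raw = cov.table.loc[~cov.table["partial"], "raw"].to_numpy()
        lam = raw.mean()
        # chi-square dispersion test against Poisson
        chi2 = ((raw - lam) ** 2 / lam).sum()
        p = sps.chi2.sf(chi2, len(raw) - 1)
        assert p > 0.001 and sps.chi2.cdf(chi2, len(raw) - 1) > 0.001


@pytest.fixture(scope="module")
def recovered(mini_config, mini_ann, mini_rnaseq):
    reads_by_sample, truth = mini_rnaseq
    sample = mini_config.samples[0].name
    records = [r.to_record() for r in reads_by_sample[sample]]
    return mini_ann, truth, sample, records


class TestTruthRecovery:
    """Planted counts are recovered exactly from the simulated reads."""

    def test_gene_counts_match_truth(self, recovered):
        ann, truth, sample, records = recovered
        unique = [r for r in records if r.unique]
        counts, _ = count_gene_sample(unique, ann.genes)
        expected = truth.counts.loc[[g.name for g in ann.genes], sample]
        assert counts.loc[expected.index].equals(expected)

    def test_repeat_family_counts_match_truth(self, recovered):
        ann, truth, sample, records = recovered
        unique = [r for r in records if r.unique]
        counts, _ = count_repeat_sample(unique, ann.repeats)
        fams = sorted({r.subtype for r in ann.repeats})
        expected = truth.counts.loc[fams, sample]
        assert counts.loc[fams].equals(expected)

    def test_unmasked_cluster_counts_match_truth(self, recovered, mini_config):
        ann, truth, sample, records = recovered
        mask = build_mask(ann.genes, ann.genome)
        counts, stats = count_pirna_sample(records, ann.clusters, mask)
        # clusters out of masking reach are recovered exactly; near-gene
        # clusters lose the reads falling in the extended genic region
        clear = [
            c.name
            for c in ann.clusters
            if not mask.overlapping(c.chrom, c.start, c.end, c.strand, "same")
        ]
        assert len(clear) > 0
        expected = truth.counts.loc[clear, sample]
        assert counts.loc[clear].equals(expected)
        masked_clusters = [c.name for c in ann.clusters if c.name not in set(clear)]
        assert (counts.loc[masked_clusters] <= truth.counts.loc[masked_clusters, sample]).all()
        assert stats["masked"] > 0
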