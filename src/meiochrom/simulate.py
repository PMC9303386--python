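"""Synthetic spermatogenic chromatin/transcriptome datasets.

Generates a miniature genome with genes, piRNA clusters and repeat
families, then stranded RNA-seq and native ChIP-seq alignments with
planted, recorded effects, so every downstream stage is testable offline.

The default configuration emulates the study design this package targets:
two conditions (WT, KO) x two stages (meiotic, post-meiotic) x two
replicates; single-end 50 nt reads; first-strand (dUTP) orientation, i.e.
every non-contaminant read is antisense to its source feature; NB-
distributed counts (variance = mu + alpha * mu^2); 101 piRNA clusters of
which 35 are planted ~25% down in the KO and 88 planted ~10-fold down
across the meiotic/post-meiotic transition; two RLTR10B-like repeat
families planted up in the KO; a four-fold ChIP enrichment of the sex
chromosomes; and a bimodal TSS enrichment kernel peaking ~500 bp either
side of the start site.

Everything is deterministic given (seed, config): identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .alignio import AlignmentRecord
from .intervals import FeatureSet, GenomeModel, GenomicInterval, make_windows
from .quantify import CountTable, make_sample_sheet


class PackingError(ValueError):
    """Requested features cannot be placed without overlap."""


class SampleSpec(NamedTuple):
    condition: str  # WT | KO
    stage: str  # meiotic | postmeiotic
    replicate: int
    library_size: int

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.stage}_rep{self.replicate}"


def default_samples(library_size: int = 200_000) -> tuple[SampleSpec, ...]:
    return tuple(
        SampleSpec(cond, stage, rep, library_size)
        for stage in ("meiotic", "postmeiotic")
        for cond in ("WT", "KO")
        for rep in (1, 2)
    )


@dataclass(frozen=True)
class TSSKernel:
    """Bimodal TSS enrichment shape: two Gaussian peaks around the start
    site (offsets in bp, strand-oriented; widths are SDs)."""

    offsets: tuple[int, int] = (-500, 500)
    widths: tuple[int, int] = (150, 150)
    weight: float = 0.15  # fraction of IP reads drawn from the kernel


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 3_000_000),
        ("chr2", 3_000_000),
        ("chr3", 3_000_000),
        ("chr4", 3_000_000),
        ("chr5", 3_000_000),
        ("chrX", 2_000_000),
        ("chrY", 800_000),
    )
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY")
    n_genes: int = 300
    gene_length: tuple[int, int] = (2_000, 10_000)
    n_pirna_clusters: int = 101
    cluster_length: tuple[int, int] = (15_000, 40_000)
    pirna_near_gene_frac: float = 0.2  # clusters planted within masking reach
    n_repeat_families: int = 12
    repeat_instances_per_family: int = 30
    repeat_length: tuple[int, int] = (300, 800)
    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    read_length: int = 50
    dispersion: float = 0.05
    frac_split: float = 0.02
    frac_multi: float = 0.03
    # planted effects (KO vs WT unless noted)
    sex_gene_lfc: float = 1.5  # sex-chromosome genes up in KO
    sex_gene_q_scale: float = 0.15  # MSCI: sex-linked genes lowly expressed
    n_auto_genes_up: int = 6
    auto_gene_up_lfc: float = 2.0
    n_auto_genes_down: int = 4
    auto_gene_down_lfc: float = -2.0
    n_pirna_down: int = 35  # ~25% decrease in KO
    pirna_down_lfc: float = -0.415
    n_pirna_stage_down: int = 88  # ~10-fold down post-meiotic vs meiotic
    pirna_stage_lfc: float = -3.32
    repeat_up_families: tuple[str, ...] = ("RLTR10B", "RLTR10B2")
    repeat_up_lfc: float = 1.5
    # ChIP-seq
    chip_enrichment_sex: float = 4.0
    tss_kernel: TSSKernel = field(default_factory=TSSKernel)
    chip_cluster_weight: float = 0.05  # IP read fraction over piRNA clusters
    chip_library_size: int = 200_000

    def __post_init__(self):
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        sex = set(self.sex_chromosomes)
        names = {n for n, _ in self.chromosomes}
        if not sex or not sex < names:
            raise ValueError("sex chromosomes must be a non-empty proper subset")
        if any(s.library_size <= 0 for s in self.samples):
            raise ValueError("library sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.frac_split + self.frac_multi < 1:
            raise ValueError("contaminant fractions must leave room for signal")

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel(self.chromosomes, self.sex_chromosomes)

    def repeat_family_names(self) -> list[str]:
        names = list(self.repeat_up_families)
        i = 1
        while len(names) < self.n_repeat_families:
            names.append(f"SynFam{i}")
            i += 1
        return names[: self.n_repeat_families]


@dataclass
class TruthTable:
    """Planted ground truth: per-feature expression model and per-window
    ChIP intensity multipliers."""

    features: pd.DataFrame  # id, class, subtype, chrom, q, lfc_condition, lfc_stage
    windows: pd.DataFrame  # chrom, start, end, multiplier

    def expected_mean(self, sample: SampleSpec, signal_fraction: float) -> pd.Series:
        lfc = self.features["lfc_condition"] * (sample.condition == "KO") + self.features[
            "lfc_stage"
        ] * (sample.stage == "postmeiotic")
        mu = self.features["q"] * sample.library_size * signal_fraction * 2.0**lfc
        return pd.Series(mu.to_numpy(), index=self.features["id"].to_numpy())

    def to_tsv(self, feature_path, window_path) -> None:
        self.features.to_csv(feature_path, sep="\t", index=False)
        self.windows.to_csv(window_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, feature_path, window_path) -> "TruthTable":
        return cls(
            pd.read_csv(feature_path, sep="\t"),
            pd.read_csv(window_path, sep="\t"),
        )


@dataclass
class Annotation:
    genome: GenomeModel
    genes: FeatureSet
    clusters: FeatureSet
    repeats: FeatureSet
    truth: TruthTable


# ---------------------------------------------------------------------------
# placement machinery


class _FreeSpace:
    """Per-chromosome free segments supporting margin-respecting placement."""

    def __init__(self, genome: GenomeModel):
        self.segments: list[tuple[str, int, int]] = [
            (chrom, 0, length) for chrom, length in genome
        ]

    def place(self, length: int, margin: int, rng: np.random.Generator) -> tuple[str, int]:
        """Place an interval of ``length`` keeping ``margin`` bp clear of
        existing features; returns (chrom, start) and splits the segment."""
        need = length + 2 * margin
        eligible = [i for i, (_, s, e) in enumerate(self.segments) if e - s >= need]
        if not eligible:
            raise PackingError(
                f"cannot place feature of length {length} with margin {margin}: "
                "no free segment large enough"
            )
        weights = np.array(
            [self.segments[i][2] - self.segments[i][1] - need + 1 for i in eligible],
            dtype=float,
        )
        i = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
        chrom, s, e = self.segments[i]
        start = int(rng.integers(s + margin, e - margin - length + 1))
        self.segments[i] = (chrom, s, start - margin)
        self.segments.insert(i + 1, (chrom, start + length + margin, e))
        self.segments = [(c, a, b) for c, a, b in self.segments if b - a > 0]
        return chrom, start

    def claim(self, chrom: str, start: int, length: int, margin: int = 0) -> None:
        """Claim a specific span (plus a trailing margin) if it lies fully
        inside one free segment; raise :class:`PackingError` otherwise."""
        end = start + length + margin
        for i, (c, s, e) in enumerate(self.segments):
            if c == chrom and s <= start and end <= e:
                self.segments[i] = (c, s, start)
                self.segments.insert(i + 1, (c, end, e))
                self.segments = [(cc, a, b) for cc, a, b in self.segments if b - a > 0]
                return
        raise PackingError(f"span {chrom}:{start}-{end} is not free")


# ---------------------------------------------------------------------------
# annotation

GENE_BIOTYPES = (
    "protein_coding",
    "protein_coding",
    "protein_coding",
    "protein_coding",
    "pseudogene",
    "polymorphic_pseudogene",
    "rRNA",
    "lincRNA",  # not in the mask list: exercises biotype filtering
    "miRNA",
)


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Place genes, piRNA clusters and repeat instances on the miniature
    genome and record the planted expression model.

    Genes never overlap. A configured fraction of piRNA clusters is placed
    on the same strand directly downstream of a gene, inside the gene's
    3 kb / 10 kb masking reach, so the genic mask is exercised; the rest
    are kept > 13 kb from any gene. Infeasible packing raises
    :class:`PackingError` rather than silently truncating.
    """
    rng = np.random.default_rng([config.seed, 1])
    genome = config.genome
    space = _FreeSpace(genome)

    genes = FeatureSet(genome=genome)
    gene_rows = []
    for i in range(config.n_genes):
        length = int(rng.integers(*config.gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = space.place(length, margin=500, rng=rng)
        biotype = GENE_BIOTYPES[rng.integers(0, len(GENE_BIOTYPES))]
        name = f"gene{i:04d}"
        genes.add(GenomicInterval(chrom, start, start + length, strand, name, "gene", biotype))
        gene_rows.append(name)

    clusters = FeatureSet(genome=genome)
    n_near = int(round(config.pirna_near_gene_frac * config.n_pirna_clusters))
    # near-gene clusters: same strand, starting < 3 kb past the gene span,
    # inside the extended mask; host genes drawn from maskable biotypes
    maskable = [g for g in genes if g.subtype != "lincRNA" and g.subtype != "miRNA"]
    ci = 0
    # the cluster begins just past the gene's placement margin, inside the
    # gene's 3 kb (upstream of a minus-strand TSS) / 10 kb (downstream of a
    # plus-strand TES) masking reach
    for hi in rng.permutation(len(maskable)):
        if ci >= n_near:
            break
        g = maskable[hi]
        length = int(rng.integers(*config.cluster_length))
        gap = int(rng.integers(0, 2_000))
        start = g.end + 500 + gap
        if start + length > genome.length(g.chrom):
            continue
        try:
            space.claim(g.chrom, start, length, margin=200)
        except PackingError:
            continue
        clusters.add(
            GenomicInterval(g.chrom, start, start + length, g.strand, f"piC{ci:03d}", "pirna_cluster")
        )
        ci += 1
    if ci < n_near:
        raise PackingError("cannot place the requested near-gene piRNA clusters")
    while ci < config.n_pirna_clusters:
        length = int(rng.integers(*config.cluster_length))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = space.place(length, margin=13_500, rng=rng)
        clusters.add(
            GenomicInterval(chrom, start, start + length, strand, f"piC{ci:03d}", "pirna_cluster")
        )
        ci += 1

    repeats = FeatureSet(genome=genome)
    families = config.repeat_family_names()
    ri = 0
    for fam in families:
        for _ in range(config.repeat_instances_per_family):
            length = int(rng.integers(*config.repeat_length))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = space.place(length, margin=200, rng=rng)
            repeats.add(
                GenomicInterval(
                    chrom, start, start + length, strand, f"{fam}/inst{ri:04d}", "repeat", fam
                )
            )
            ri += 1

    truth = _build_truth(config, genome, genes, clusters, repeats, rng)
    return Annotation(genome, genes, clusters, repeats, truth)


def _build_truth(config, genome, genes, clusters, repeats, rng) -> TruthTable:
    rows = []
    gene_list = list(genes)
    auto_genes = [g for g in gene_list if g.chrom not in genome.sex_chromosomes]
    picked = rng.choice(
        len(auto_genes),
        size=min(config.n_auto_genes_up + config.n_auto_genes_down, len(auto_genes)),
        replace=False,
    )
    up = {auto_genes[i].name for i in picked[: config.n_auto_genes_up]}
    down = {auto_genes[i].name for i in picked[config.n_auto_genes_up :]}
    for g in gene_list:
        if g.chrom in genome.sex_chromosomes:
            lfc = config.sex_gene_lfc
        elif g.name in up:
            lfc = config.auto_gene_up_lfc
        elif g.name in down:
            lfc = config.auto_gene_down_lfc
        else:
            lfc = 0.0
        q = float(rng.lognormal(mean=np.log(3e-3 / max(len(gene_list), 1)), sigma=1.0))
        if g.chrom in genome.sex_chromosomes:
            # meiotic sex-chromosome inactivation keeps sex-linked
            # baseline expression low
            q *= config.sex_gene_q_scale
        rows.append((g.name, "gene", g.subtype, g.chrom, q, lfc, 0.0))

    cluster_list = list(clusters)
    order = rng.permutation(len(cluster_list))
    down_cl = {cluster_list[i].name for i in order[: config.n_pirna_down]}
    order2 = rng.permutation(len(cluster_list))
    stage_down = {cluster_list[i].name for i in order2[: config.n_pirna_stage_down]}
    for c in cluster_list:
        q = float(rng.lognormal(mean=np.log(4e-3 / max(len(cluster_list), 1)), sigma=0.8))
        rows.append(
            (
                c.name,
                "pirna_cluster",
                "",
                c.chrom,
                q,
                config.pirna_down_lfc if c.name in down_cl else 0.0,
                config.pirna_stage_lfc if c.name in stage_down else 0.0,
            )
        )

    for fam in config.repeat_family_names():
        q = float(rng.lognormal(mean=np.log(1e-3 / max(config.n_repeat_families, 1)), sigma=0.5))
        lfc = config.repeat_up_lfc if fam in config.repeat_up_families else 0.0
        rows.append((fam, "repeat_family", fam, ".", q, lfc, 0.0))

    features = pd.DataFrame(
        rows,
        columns=["id", "class", "subtype", "chrom", "q", "lfc_condition", "lfc_stage"],
    )
    # normalize q to sum to 1: q is the expected read fraction at baseline
    features["q"] = features["q"] / features["q"].sum()

    wins = make_windows(genome, 40_000)
    windows = pd.DataFrame(
        {
            "chrom": [w.chrom for w in wins],
            "start": [w.start for w in wins],
            "end": [w.end for w in wins],
            "multiplier": [
                config.chip_enrichment_sex if w.chrom in genome.sex_chromosomes else 1.0
                for w in wins
            ],
        }
    )
    return TruthTable(features, windows)


# ---------------------------------------------------------------------------
# read emission


class SamRead(NamedTuple):
    qname: str
    chrom: str
    pos: int  # 0-based leftmost
    blocks: tuple[tuple[int, int], ...]
    strand: str
    nh: int  # hit count; 1 = unique

    def to_record(self) -> AlignmentRecord:
        return AlignmentRecord(self.qname, self.chrom, self.blocks, self.strand, self.nh == 1)


def _sam_header(genome: GenomeModel) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome],
    }


def write_sam(reads: list[SamRead], genome: GenomeModel, path) -> None:
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.qname
            a.reference_name = r.chrom
            a.reference_start = r.pos
            a.mapping_quality = 50 if r.nh == 1 else 0
            a.flag = 16 if r.strand == "-" else 0
            cig = []
            prev_end = None
            for bs, be in r.blocks:
                if prev_end is not None:
                    cig.append((3, bs - prev_end))  # N
                cig.append((0, be - bs))  # M
                prev_end = be
            a.cigartuples = cig
            a.set_tag("NH", r.nh)
            fh.write(a)


def _feature_reads(
    rng: np.random.Generator,
    iv: GenomicInterval,
    count: int,
    read_length: int,
    prefix: str,
) -> list[SamRead]:
    """Uniformly placed single-block reads antisense to the feature."""
    if count == 0:
        return []
    hi = max(iv.start + 1, iv.end - read_length)
    starts = rng.integers(iv.start, hi, size=count)
    strand = "-" if iv.strand == "+" else "+"
    return [
        SamRead(
            f"{prefix}_{i}",
            iv.chrom,
            int(s),
            ((int(s), min(int(s) + read_length, iv.end)),),
            strand,
            1,
        )
        for i, s in enumerate(starts)
    ]


def simulate_rnaseq(
    config: SimulationConfig, ann: Annotation
) -> tuple[dict[str, list[SamRead]], CountTable]:
    """Stranded RNA-seq alignments per sample plus the true count table.

    Per-feature counts are NB(mean = L_s * q_i * 2^(lfc_cond*[KO] +
    lfc_stage*[post]), dispersion); reads are uniform within the feature
    and antisense to it (first-strand convention). ``frac_split`` of extra
    reads are emitted as two-block (split-mapped) contaminants and
    ``frac_multi`` as non-unique contaminants; neither enters the truth
    counts.
    """
    rng = np.random.default_rng([config.seed, 2])
    signal_fraction = 1.0 - config.frac_split - config.frac_multi
    by_id = {}
    for fs in (ann.genes, ann.clusters):
        for iv in fs:
            by_id[iv.name] = [iv]
    for iv in ann.repeats:
        by_id.setdefault(iv.subtype, []).append(iv)

    feats = ann.truth.features
    reads_by_sample: dict[str, list[SamRead]] = {}
    truth_cols = {}
    for sample in config.samples:
        mu = ann.truth.expected_mean(sample, signal_fraction).to_numpy()
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        reads: list[SamRead] = []
        for (fid, cls), n in zip(feats[["id", "class"]].itertuples(index=False), counts):
            if n == 0:
                continue
            instances = by_id[fid]
            if len(instances) == 1:
                reads += _feature_reads(
                    rng, instances[0], int(n), config.read_length, f"{sample.name}_{fid}"
                )
            else:  # repeat family: spread count over instances
                alloc = rng.multinomial(int(n), np.full(len(instances), 1 / len(instances)))
                for j, (iv, nj) in enumerate(zip(instances, alloc)):
                    reads += _feature_reads(
                        rng, iv, int(nj), config.read_length, f"{sample.name}_{fid}_{j}"
                    )
        n_signal = len(reads)
        n_split = rng.poisson(config.frac_split * sample.library_size)
        n_multi = rng.poisson(config.frac_multi * sample.library_size)
        reads += _contaminant_reads(rng, ann, n_split, n_multi, config, sample.name)
        order = rng.permutation(len(reads))
        reads_by_sample[sample.name] = [reads[i] for i in order]
        truth_cols[sample.name] = pd.Series(counts, index=feats["id"])
        assert len(reads) == n_signal + n_split + n_multi

    sheet = make_sample_sheet(
        {
            "sample": s.name,
            "condition": s.condition,
            "stage": s.stage,
            "assay": "rnaseq",
            "library_size": s.library_size,
            "replicate": s.replicate,
        }
        for s in config.samples
    )
    truth = CountTable(pd.DataFrame(truth_cols), sheet)
    return reads_by_sample, truth


def _contaminant_reads(rng, ann, n_split, n_multi, config, prefix) -> list[SamRead]:
    # split contaminants live inside clusters (the artifact class the
    # split-read filter exists for); multi-mappers land anywhere
    out = []
    hosts = list(ann.clusters) or list(ann.genes)
    half = config.read_length // 2
    gap = 100
    for i in range(n_split):
        iv = hosts[rng.integers(0, len(hosts))]
        span = 2 * half + gap
        start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - span)))
        blocks = ((start, start + half), (start + half + gap, start + span))
        strand = "-" if iv.strand == "+" else "+"
        out.append(SamRead(f"{prefix}_split_{i}", iv.chrom, start, blocks, strand, 1))
    chroms = list(ann.genome)
    lengths = np.array([l for _, l in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n_multi, p=lengths / lengths.sum())
    for i, ci in enumerate(picks):
        chrom, length = chroms[ci]
        start = int(rng.integers(0, max(1, length - config.read_length)))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            SamRead(
                f"{prefix}_multi_{i}",
                chrom,
                start,
                ((start, start + config.read_length),),
                strand,
                2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ChIP-seq


def simulate_chipseq(
    config: SimulationConfig, ann: Annotation, stage: str = "meiotic"
) -> dict[str, list[SamRead]]:
    """IP and input alignments for one stage.

    Input reads are uniform over the genome. IP intensity is the product
    of a per-window multiplier (``chip_enrichment_sex`` on sex
    chromosomes), a bimodal TSS kernel near genes, and a cluster-occupancy
    component proportional to planted cluster expression; window counts
    are Poisson and positions uniform within the window.
    """
    rng = np.random.default_rng([config.seed, 3, 0 if stage == "meiotic" else 1])
    genome = ann.genome
    n = config.chip_library_size
    kernel = config.tss_kernel
    w_kernel = kernel.weight
    w_cluster = config.chip_cluster_weight
    out: dict[str, list[SamRead]] = {}

    win = ann.truth.windows
    for label, enriched in (("input", False), ("IP", True)):
        reads: list[SamRead] = []
        mult = win["multiplier"].to_numpy() if enriched else np.ones(len(win))
        lengths = (win["end"] - win["start"]).to_numpy(dtype=float)
        weight = lengths * mult
        n_bg = n * (1.0 - w_kernel - w_cluster) if enriched else n
        lam = n_bg * weight / weight.sum()
        counts = rng.poisson(lam)
        for (chrom, start, end), c in zip(
            win[["chrom", "start", "end"]].itertuples(index=False), counts
        ):
            if c == 0:
                continue
            starts = rng.integers(start, max(start + 1, end - config.read_length), size=c)
            for i, s in enumerate(starts):
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(
                    SamRead(
                        f"{stage}_{label}_bg_{chrom}_{start}_{i}",
                        chrom,
                        int(s),
                        ((int(s), int(s) + config.read_length),),
                        strand,
                        1,
                    )
                )
        if enriched and w_kernel > 0:
            reads += _kernel_reads(rng, ann, config, n * w_kernel, stage)
        if enriched and w_cluster > 0:
            reads += _cluster_occupancy_reads(rng, ann, config, n * w_cluster, stage)
        order = rng.permutation(len(reads))
        out[f"{label}_{stage}"] = [reads[i] for i in order]
    return out


def _sex_mult(config, genome, chrom) -> float:
    return config.chip_enrichment_sex if chrom in genome.sex_chromosomes else 1.0


def _kernel_reads(rng, ann, config, total, stage) -> list[SamRead]:
    genes = list(ann.genes)
    kernel = config.tss_kernel
    mult = np.array([_sex_mult(config, ann.genome, g.chrom) for g in genes])
    lam = total * mult / mult.sum()
    counts = rng.poisson(lam)
    reads = []
    for gi, (g, c) in enumerate(zip(genes, counts)):
        if c == 0:
            continue
        which = rng.integers(0, 2, size=c)
        offsets = rng.normal(
            np.array(kernel.offsets)[which], np.array(kernel.widths)[which]
        ).round()
        sign = 1 if g.strand == "+" else -1
        pos = g.tss + sign * offsets.astype(int)
        pos = np.clip(pos, 0, ann.genome.length(g.chrom) - config.read_length)
        for i, p in enumerate(pos):
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                SamRead(
                    f"{stage}_IP_tss_{gi}_{i}",
                    g.chrom,
                    int(p),
                    ((int(p), int(p) + config.read_length),),
                    strand,
                    1,
                )
            )
    return reads


def _cluster_occupancy_reads(rng, ann, config, total, stage) -> list[SamRead]:
    clusters = list(ann.clusters)
    feats = ann.truth.features.set_index("id")
    q = np.array([feats.loc[c.name, "q"] for c in clusters], dtype=float)
    mult = np.array([_sex_mult(config, ann.genome, c.chrom) for c in clusters])
    weight = q * mult
    lam = total * weight / weight.sum()
    counts = rng.poisson(lam)
    reads = []
    for ci, (c, n) in enumerate(zip(clusters, counts)):
        if n == 0:
            continue
        starts = rng.integers(c.start, max(c.start + 1, c.end - config.read_length), size=n)
        for i, s in enumerate(starts):
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                SamRead(
                    f"{stage}_IP_piC_{ci}_{i}",
                    c.chrom,
                    int(s),
                    ((int(s), int(s) + config.read_length),),
                    strand,
                    1,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# count-level simulation (for statistical benchmarks)


def simulate_count_table(
    n_features: int,
    lfc: np.ndarray | float = 0.0,
    dispersion: np.ndarray | float = 0.05,
    n_per_group: int = 2,
    mean_log: float = np.log(200.0),
    mean_sd: float = 1.0,
    seed: int = 0,
    feature_prefix: str = "f",
    size_factors: np.ndarray | None = None,
) -> tuple[CountTable, np.ndarray]:
    """NB count table for a WT-vs-KO design without read-level simulation.

    Per-feature baseline means are lognormal(``mean_log``, ``mean_sd``);
    KO means are scaled by 2**lfc; counts are NB with
    variance = mu + dispersion * mu^2. Returns the table and the true
    per-feature log2 fold changes.
    """
    rng = np.random.default_rng(seed)
    lfc = np.broadcast_to(np.asarray(lfc, dtype=float), (n_features,))
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_features,))
    q = rng.lognormal(mean_log, mean_sd, size=n_features)
    names, conds = [], []
    for cond in ("WT", "KO"):
        for rep in range(1, n_per_group + 1):
            names.append(f"{cond}_rep{rep}")
            conds.append(cond)
    if size_factors is None:
        size_factors = np.ones(len(names))
    cols = {}
    for j, (name, cond) in enumerate(zip(names, conds)):
        mu = q * (2.0**lfc if cond == "KO" else 1.0) * size_factors[j]
        counts = np.where(
            disp > 0,
            rng.negative_binomial(
                np.where(disp > 0, 1.0 / np.maximum(disp, 1e-12), 1.0),
                np.where(
                    disp > 0,
                    (1.0 / np.maximum(disp, 1e-12))
                    / (1.0 / np.maximum(disp, 1e-12) + mu),
                    0.5,
                ),
            ),
            rng.poisson(mu),
        )
        cols[name] = counts
    counts = pd.DataFrame(cols, index=[f"{feature_prefix}{i:05d}" for i in range(n_features)])
    sheet = make_sample_sheet(
        {
            "sample": name,
            "condition": cond,
            "stage": "meiotic",
            "assay": "rnaseq",
            "library_size": int(counts[name].sum()),
        }
        for name, cond in zip(names, conds)
    )
    return CountTable(counts, sheet), lfc.copy()
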