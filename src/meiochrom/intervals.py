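"""Genomic interval algebra.

All internal coordinates are 0-based half-open (BED convention). GTF input,
which is 1-based closed, is converted at parse time. Strand is one of
``'+'``, ``'-'`` or ``'.'`` (unstranded).

The transcription start site (TSS) of a stranded interval is its 5' end:
``start`` on the plus strand, ``end - 1`` on the minus strand; the
transcript end site (TES) is the symmetric 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: Gene biotypes whose (extended) loci are masked before piRNA cluster
#: quantification: immunoglobulin segments, mitochondrial structural RNAs,
#: protein-coding genes, pseudogenes and rRNA.
DEFAULT_MASK_BIOTYPES = frozenset(
    {
        "IG_C_gene",
        "IG_D_gene",
        "IG_J_gene",
        "IG_V_gene",
        "Mt_rRNA",
        "Mt_tRNA",
        "polymorphic_pseudogene",
        "protein_coding",
        "pseudogene",
        "rRNA",
    }
)


class GenomeModel:
    """Ordered chromosome names and lengths, with a designated sex subset.

    Parameters
    ----------
    chromosomes
        Iterable of ``(name, length)`` pairs; order is preserved and defines
        genome order for plots and tables.
    sex_chromosomes
        Names of the sex chromosomes; must be a subset of ``chromosomes``.
    """

    def __init__(
        self,
        chromosomes: Iterable[tuple[str, int]],
        sex_chromosomes: Iterable[str] = (),
    ):
        self._lengths: dict[str, int] = {}
        for name, length in chromosomes:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[name] = int(length)
        self.sex_chromosomes = frozenset(sex_chromosomes)
        unknown = self.sex_chromosomes - set(self._lengths)
        if unknown:
            raise ValueError(f"sex chromosomes not in genome: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def autosomes(self) -> list[str]:
        return [n for n in self._lengths if n not in self.sex_chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __len__(self) -> int:
        return len(self._lengths)

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeModel)
            and list(self) == list(other)
            and self.sex_chromosomes == other.sex_chromosomes
        )

    def __repr__(self) -> str:
        return f"GenomeModel({len(self)} chromosomes, sex={sorted(self.sex_chromosomes)})"

    # -- chrom.sizes I/O ---------------------------------------------------

    @classmethod
    def from_chrom_sizes(cls, path, sex_chromosomes: Iterable[str] = ()) -> "GenomeModel":
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            pairs.append((name, int(length)))
        return cls(pairs, sex_chromosomes)

    def to_chrom_sizes(self, path) -> None:
        Path(path).write_text("".join(f"{n}\t{l}\n" for n, l in self))


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span with strand, identity and feature class."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    feature_class: str = "other"  # gene | pirna_cluster | repeat | window | other
    subtype: str = ""  # gene biotype, repeat family, ...
    partial: bool = False  # short terminal window flag

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )

    def validate(self, genome: GenomeModel) -> None:
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome: {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"{self.name}: end {self.end} beyond {self.chrom} "
                f"length {genome.length(self.chrom)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """5' base coordinate (start on +, end-1 on -)."""
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError("TSS undefined for unstranded interval")

    @property
    def tes(self) -> int:
        """3' base coordinate."""
        if self.strand == "+":
            return self.end - 1
        if self.strand == "-":
            return self.start
        raise ValueError("TES undefined for unstranded interval")


def overlaps(a: GenomicInterval, b: GenomicInterval, strand_mode: str = "ignore") -> bool:
    """1-bp half-open overlap test with a strand predicate.

    ``strand_mode`` is ``'ignore'``, ``'same'`` or ``'opposite'``; abutting
    intervals never overlap. ``same``/``opposite`` require both strands set.
    """
    if a.chrom != b.chrom:
        return False
    if not (a.start < b.end and b.start < a.end):
        return False
    return _strand_ok(a.strand, b.strand, strand_mode)


def _strand_ok(s1: str, s2: str, mode: str) -> bool:
    if mode == "ignore":
        return True
    if mode not in ("same", "opposite"):
        raise ValueError(f"unknown strand_mode {mode!r}")
    if s1 == "." or s2 == ".":
        return False
    return (s1 == s2) if mode == "same" else (s1 != s2)


def extend_interval(
    iv: GenomicInterval, upstream: int, downstream: int, genome: GenomeModel
) -> GenomicInterval:
    """Extend a stranded interval upstream of its TSS and downstream of its
    TES, clamped to the chromosome bounds.

    On the plus strand the result is ``[start - upstream, end + downstream)``;
    on the minus strand ``[start - downstream, end + upstream)``.
    """
    if iv.strand not in ("+", "-"):
        raise ValueError("cannot extend unstranded interval: orientation undefined")
    if upstream < 0 or downstream < 0:
        raise ValueError("extensions must be non-negative")
    if iv.strand == "+":
        start, end = iv.start - upstream, iv.end + downstream
    else:
        start, end = iv.start - downstream, iv.end + upstream
    start = max(0, start)
    end = min(genome.length(iv.chrom), end)
    return replace(iv, start=start, end=end)


class FeatureSet:
    """A collection of :class:`GenomicInterval` indexed by chromosome for
    overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), genome: GenomeModel | None = None):
        self._intervals: list[GenomicInterval] = []
        self._trees: dict[str, IntervalTree] = {}
        self.genome = genome
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        if self.genome is not None:
            iv.validate(self.genome)
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str = ".", strand_mode: str = "ignore"
    ) -> list[GenomicInterval]:
        """All member intervals overlapping ``[start, end)`` on ``chrom``
        under the given strand predicate (``strand`` is the query strand)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        if strand_mode != "ignore":
            hits = [h for h in hits if _strand_ok(strand, h.strand, strand_mode)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.name))
        return hits

    # -- BED6 I/O (bit-exact round trip) -----------------------------------

    def to_bed6(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self._intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
                )

    @classmethod
    def from_bed6(
        cls,
        path,
        genome: GenomeModel | None = None,
        feature_class: str = "other",
        name_is_family: bool = False,
    ) -> "FeatureSet":
        """Read BED6. With ``name_is_family`` the name field's prefix before
        the last ``'/'`` (or the whole name) is stored as ``subtype`` — the
        RepeatMasker-style family label."""
        fs = cls(genome=genome)
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            subtype = name.rsplit("/", 1)[0] if name_is_family else ""
            fs.add(
                GenomicInterval(
                    chrom, int(start), int(end), strand, name, feature_class, subtype
                )
            )
        return fs

    # -- GTF I/O -----------------------------------------------------------

    @classmethod
    def from_gtf(cls, path, genome: GenomeModel | None = None, feature_type: str = "gene") -> "FeatureSet":
        """Read gene records from a GTF (1-based closed coordinates,
        converted to 0-based half-open). Attributes ``gene_id`` and
        ``gene_biotype`` populate ``name`` and ``subtype``."""
        fs = cls(genome=genome)
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != feature_type:
                continue
            attr = _parse_gtf_attrs(attrs)
            fs.add(
                GenomicInterval(
                    chrom,
                    int(start) - 1,
                    int(end),
                    strand,
                    attr.get("gene_id", "."),
                    "gene",
                    attr.get("gene_biotype", ""),
                )
            )
        return fs

    def to_gtf(self, path, source: str = "meiochrom") -> None:
        with open(path, "w") as fh:
            for iv in self._intervals:
                attrs = f'gene_id "{iv.name}"; gene_biotype "{iv.subtype}";'
                fh.write(
                    f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def make_windows(genome: GenomeModel, width: int) -> FeatureSet:
    """Tile every chromosome with non-overlapping windows of ``width`` bp.

    The terminal window of a chromosome whose length is not a multiple of
    ``width`` is emitted but flagged ``partial``; chromosome-level summaries
    use full windows only so that per-window means stay comparable.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    fs = FeatureSet(genome=genome)
    for chrom, length in genome:
        for i, start in enumerate(range(0, length, width)):
            end = min(start + width, length)
            fs.add(
                GenomicInterval(
                    chrom,
                    start,
                    end,
                    ".",
                    f"{chrom}:{start}-{end}",
                    "window",
                    partial=(end - start < width),
                )
            )
    return fs


def build_mask(
    genes: FeatureSet,
    genome: GenomeModel,
    biotypes: frozenset[str] | set[str] = DEFAULT_MASK_BIOTYPES,
    upstream: int = 3000,
    downstream: int = 10000,
    merge: bool = True,
) -> FeatureSet:
    """Genic mask for piRNA cluster quantification.

    Every gene whose biotype is in ``biotypes`` is extended ``upstream`` bp
    before its TSS and ``downstream`` bp past its TES (to absorb polymerase
    read-through), preserving strand. Overlapping same-strand mask intervals
    are merged; strand is retained because downstream overlap tests are
    strand-aware.
    """
    extended = [
        extend_interval(g, upstream, downstream, genome)
        for g in genes
        if g.subtype in biotypes
    ]
    if not merge:
        return FeatureSet(extended, genome=genome)
    merged: list[GenomicInterval] = []
    keyfn = lambda iv: (iv.chrom, iv.strand, iv.start, iv.end)
    for iv in sorted(extended, key=keyfn):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and merged[-1].strand == iv.strand
            and iv.start <= merged[-1].end
        ):
            prev = merged[-1]
            merged[-1] = replace(prev, end=max(prev.end, iv.end), name=prev.name)
        else:
            merged.append(replace(iv, feature_class="other", subtype="mask"))
    return FeatureSet(merged, genome=genome)
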