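"""Alignment records and read-level filters.

Reads arrive as SAM/BAM (via pysam) or as the BED12 dialect the simulator can
emit. A record carries its aligned blocks (split at skipped-region ``N``
operators, not at small deletions), its strand, and a uniqueness flag.

Uniqueness follows the aligner's hit-count tag (``NH == 1``) when present
and falls back to a mapping-quality threshold (MAPQ >= 30) otherwise, a
proxy for "only uniquely aligned reads retained".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .intervals import FeatureSet, GenomeModel, _strand_ok

MAPQ_UNIQUE = 30


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped single-end read."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]  # sorted, non-overlapping, half-open
    strand: str  # '+' or '-'
    unique: bool = True

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("alignment must have at least one block")
        prev_end = -1
        for start, end in self.blocks:
            if not (0 <= start < end) or start < prev_end:
                raise ValueError(f"malformed blocks {self.blocks}")
            prev_end = end
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid read strand {self.strand!r}")

    @property
    def split(self) -> bool:
        return len(self.blocks) > 1

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def five_prime(self) -> int:
        """Coordinate of the read's 5'-most aligned base."""
        return self.start if self.strand == "+" else self.end - 1


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference blocks from CIGAR, splitting only at N (skipped region).

    M/=/X and D extend the current block; N closes it; I/S/H/P are
    query-only or silent.
    """
    blocks = []
    start = cur = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur += length
        elif op == 3:  # N: splice/skip → new block
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
        # 1 (I), 4 (S), 5 (H), 6 (P): no reference advance
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_alignments(path, genome: GenomeModel) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM/BAM file (or ``.bed12``).

    Unmapped records are skipped. A record on a chromosome absent from
    ``genome`` raises with the offending name.
    """
    path = str(path)
    if path.endswith((".bed12", ".bed")):
        yield from _read_bed12(path, genome)
        return
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                raise ValueError(f"alignment on unknown chromosome: {chrom!r}")
            if rec.has_tag("NH"):
                unique = rec.get_tag("NH") == 1
            else:
                unique = rec.mapping_quality >= MAPQ_UNIQUE
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=chrom,
                blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples or ()),
                strand="-" if rec.is_reverse else "+",
                unique=unique,
            )


def _read_bed12(path, genome: GenomeModel) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            chrom, start = f[0], int(f[1])
            if chrom not in genome:
                raise ValueError(f"alignment on unknown chromosome: {chrom!r}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            yield AlignmentRecord(
                read_id=f[3],
                chrom=chrom,
                blocks=blocks,
                strand=f[5],
                unique=int(f[4]) >= MAPQ_UNIQUE,
            )


@dataclass
class FilterStats:
    """Per-reason removal counts; reasons sum to input - passed."""

    input: int = 0
    passed: int = 0
    not_unique: int = 0
    split: int = 0
    masked: int = 0

    def check(self) -> None:
        assert self.input - self.passed == self.not_unique + self.split + self.masked

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "passed": self.passed,
            "not_unique": self.not_unique,
            "split": self.split,
            "masked": self.masked,
        }


def filter_reads(
    reads: Iterable[AlignmentRecord],
    require_unique: bool = True,
    drop_split: bool = False,
    mask: FeatureSet | None = None,
    mask_strand_mode: str = "opposite",
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Apply the read-level filters in order: uniqueness, split mapping,
    genic-mask overlap.

    A read is masked out when any of its blocks overlaps (>= 1 bp) any mask
    interval under ``mask_strand_mode``; with ``'opposite'`` (the
    first-strand library convention) a minus-strand read is removed by a
    plus-strand mask interval and vice versa. Order is preserved.
    """
    kept: list[AlignmentRecord] = []
    stats = FilterStats()
    for read in reads:
        stats.input += 1
        if require_unique and not read.unique:
            stats.not_unique += 1
            continue
        if drop_split and read.split:
            stats.split += 1
            continue
        if mask is not None and _hits_mask(read, mask, mask_strand_mode):
            stats.masked += 1
            continue
        stats.passed += 1
        kept.append(read)
    stats.check()
    return kept, stats


def _hits_mask(read: AlignmentRecord, mask: FeatureSet, mode: str) -> bool:
    for start, end in read.blocks:
        if mask.overlapping(read.chrom, start, end, strand=read.strand, strand_mode=mode):
            return True
    return False
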