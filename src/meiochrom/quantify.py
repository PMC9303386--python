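"""Read counting: genes, piRNA clusters (with genic masking), repeat
families, and genome-wide window coverage.

Counting conventions
--------------------
* Gene counting re-implements union-mode semantics for stranded libraries:
  a read counts for a gene only if every aligned block overlaps that gene
  under the strand mode (default ``opposite``, the first-strand dUTP
  convention) and no other gene overlaps the read at all; reads touching
  two genes are dropped as ambiguous.
* piRNA cluster counting first removes non-unique reads, split-mapped reads
  and reads overlapping the extended genic mask on the opposite strand,
  then assigns survivors to clusters by opposite-strand overlap.
* Repeat counting ignores strand (RepeatMasker families contain both
  orientations); a read overlapping instances of several families counts
  in each.
* Window coverage assigns each read to the window containing its 5'-most
  base and normalizes to 10 million mapped reads.

Every counter returns assignment statistics so that
``assigned + dropped == input`` is auditable at each stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignio import AlignmentRecord, FilterStats, filter_reads
from .intervals import FeatureSet, GenomicInterval

NORM_TOTAL = 10_000_000  # coverage normalization target: 10 million reads


def make_sample_sheet(samples: Iterable[Mapping]) -> pd.DataFrame:
    """Sample sheet with condition, stage, assay and library size per sample."""
    df = pd.DataFrame(list(samples))
    df = df.set_index("sample")
    for col in ("condition", "stage", "assay", "library_size"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    return df


@dataclass
class CountTable:
    """Features x samples integer counts plus the sample sheet."""

    counts: pd.DataFrame  # rows: feature ids, columns: sample ids
    samples: pd.DataFrame  # index: sample ids

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sheet: {sorted(missing)}")
        self.counts = self.counts.astype(np.int64)

    @property
    def library_sizes(self) -> pd.Series:
        return self.samples.loc[self.counts.columns, "library_size"].astype(float)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts, samples)

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        return CountTable(self.counts[sample_ids], self.samples.loc[sample_ids])


# ---------------------------------------------------------------------------
# gene counting


def count_gene_sample(
    reads: Iterable[AlignmentRecord],
    genes: FeatureSet,
    strand_mode: str = "opposite",
) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample's reads per gene (union-mode, ambiguity-dropping)."""
    counts = {g.name: 0 for g in genes}
    stats = {"input": 0, "assigned": 0, "ambiguous": 0, "no_feature": 0}
    for read in reads:
        stats["input"] += 1
        hit_any: set[str] = set()
        hit_all: set[str] | None = None
        for start, end in read.blocks:
            hits = {
                g.name
                for g in genes.overlapping(
                    read.chrom, start, end, strand=read.strand, strand_mode=strand_mode
                )
            }
            hit_any |= hits
            hit_all = hits if hit_all is None else (hit_all & hits)
        if not hit_any:
            stats["no_feature"] += 1
        elif len(hit_any) > 1:
            stats["ambiguous"] += 1
        elif hit_all:
            counts[next(iter(hit_all))] += 1
            stats["assigned"] += 1
        else:  # single gene but not covered by every block
            stats["no_feature"] += 1
    return pd.Series(counts, dtype=np.int64), stats


def count_genes(
    reads_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    genes: FeatureSet,
    sample_sheet: pd.DataFrame,
    strand_mode: str = "opposite",
) -> tuple[CountTable, dict[str, dict[str, int]]]:
    cols, stats = {}, {}
    for sample, reads in reads_by_sample.items():
        cols[sample], stats[sample] = count_gene_sample(reads, genes, strand_mode)
    return CountTable(pd.DataFrame(cols), sample_sheet), stats


# ---------------------------------------------------------------------------
# piRNA cluster counting


def count_pirna_sample(
    reads: Iterable[AlignmentRecord],
    clusters: FeatureSet,
    mask: FeatureSet,
    multi: str = "all",
) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample's reads per piRNA cluster after the three-rule
    pre-filter (unique only, no split reads, no opposite-strand genic-mask
    overlap).

    ``multi='all'`` counts a read in every cluster it overlaps (clusters
    rarely overlap); ``multi='drop'`` drops multi-cluster reads.
    """
    surviving, fstats = filter_reads(
        reads, require_unique=True, drop_split=True, mask=mask, mask_strand_mode="opposite"
    )
    counts = {c.name: 0 for c in clusters}
    stats = {
        "input": fstats.input,
        "not_unique": fstats.not_unique,
        "split": fstats.split,
        "masked": fstats.masked,
        "assigned": 0,
        "multi_cluster": 0,
        "no_feature": 0,
    }
    for read in surviving:
        hits: set[str] = set()
        for start, end in read.blocks:
            hits |= {
                c.name
                for c in clusters.overlapping(
                    read.chrom, start, end, strand=read.strand, strand_mode="opposite"
                )
            }
        if not hits:
            stats["no_feature"] += 1
        elif len(hits) == 1 or multi == "all":
            for name in hits:
                counts[name] += 1
            stats["assigned"] += 1
            if len(hits) > 1:
                stats["multi_cluster"] += 1
        else:
            stats["multi_cluster"] += 1
    return pd.Series(counts, dtype=np.int64), stats


def count_pirna_clusters(
    reads_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    clusters: FeatureSet,
    mask: FeatureSet,
    sample_sheet: pd.DataFrame,
    multi: str = "all",
) -> tuple[CountTable, dict[str, dict[str, int]]]:
    cols, stats = {}, {}
    for sample, reads in reads_by_sample.items():
        cols[sample], stats[sample] = count_pirna_sample(reads, clusters, mask, multi)
    return CountTable(pd.DataFrame(cols), sample_sheet), stats


# ---------------------------------------------------------------------------
# repeat family counting


def count_repeat_sample(
    reads: Iterable[AlignmentRecord],
    repeat_instances: FeatureSet,
    strand_mode: str = "ignore",
) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample's reads per repeat family (rows are families; a read
    may count in more than one family)."""
    families = sorted({r.subtype for r in repeat_instances})
    counts = {f: 0 for f in families}
    stats = {"input": 0, "assigned": 0, "no_feature": 0, "multi_family": 0}
    for read in reads:
        stats["input"] += 1
        hits: set[str] = set()
        for start, end in read.blocks:
            hits |= {
                r.subtype
                for r in repeat_instances.overlapping(
                    read.chrom, start, end, strand=read.strand, strand_mode=strand_mode
                )
            }
        if not hits:
            stats["no_feature"] += 1
            continue
        stats["assigned"] += 1
        if len(hits) > 1:
            stats["multi_family"] += 1
        for fam in hits:
            counts[fam] += 1
    return pd.Series(counts, dtype=np.int64), stats


def count_repeat_families(
    reads_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    repeat_instances: FeatureSet,
    sample_sheet: pd.DataFrame,
    strand_mode: str = "ignore",
) -> tuple[CountTable, dict[str, dict[str, int]]]:
    cols, stats = {}, {}
    for sample, reads in reads_by_sample.items():
        cols[sample], stats[sample] = count_repeat_sample(reads, repeat_instances, strand_mode)
    return CountTable(pd.DataFrame(cols), sample_sheet), stats


def rpm_filter(
    table: CountTable, floor: float = 5.0, mode: str = "all"
) -> tuple[CountTable, list[str]]:
    """Exclude low-abundance families by reads-per-million.

    ``RPM(f, s) = count * 1e6 / library_size``. With ``mode='all'`` (default)
    a family is excluded only when it is below ``floor`` in every sample;
    ``mode='any'`` is the stricter reading (excluded if below the floor in
    any sample). Returns the filtered table and the excluded family list.
    """
    lib = table.library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    rpm = table.counts * 1e6 / lib
    if mode == "all":
        keep = (rpm >= floor).any(axis=1)
    elif mode == "any":
        keep = (rpm >= floor).all(axis=1)
    else:
        raise ValueError(f"unknown rpm_filter mode {mode!r}")
    excluded = sorted(table.counts.index[~keep])
    return CountTable(table.counts[keep], table.samples), excluded


# ---------------------------------------------------------------------------
# window coverage


@dataclass
class WindowCoverage:
    """Per-window raw counts and 10M-normalized values for one sample."""

    table: pd.DataFrame  # columns: chrom, start, end, partial, raw, norm
    sample: str
    library_size: float

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.table.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.norm:.6g}\n")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample: str, library_size: float) -> "WindowCoverage":
        return cls(pd.read_csv(path, sep="\t"), sample, library_size)


def window_coverage(
    reads: Iterable[AlignmentRecord],
    windows: FeatureSet,
    library_size: float,
    sample: str = "",
    norm_total: float = NORM_TOTAL,
) -> tuple[WindowCoverage, dict[str, int]]:
    """Count reads per genome window by the 5'-most base, normalized to
    ``norm_total`` (10 million) reads.

    Assignment by a single base keeps the conservation audit exact:
    every read on a tiled chromosome lands in exactly one window.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    # windows tile each chromosome: locate by division on a per-chrom grid
    wlist = list(windows)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in wlist:
        by_chrom.setdefault(w.chrom, []).append(w)
    width = max(len(w) for w in wlist)
    index = {(w.chrom, w.start // width): i for i, w in enumerate(wlist)}
    raw = np.zeros(len(wlist), dtype=np.int64)
    stats = {"input": 0, "assigned": 0, "no_window": 0}
    for read in reads:
        stats["input"] += 1
        key = (read.chrom, read.five_prime // width)
        i = index.get(key)
        if i is None:
            stats["no_window"] += 1
            continue
        raw[i] += 1
        stats["assigned"] += 1
    scale = norm_total / library_size
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in wlist],
            "start": [w.start for w in wlist],
            "end": [w.end for w in wlist],
            "partial": [w.partial for w in wlist],
            "raw": raw,
            "norm": raw * scale,
        }
    )
    return WindowCoverage(table, sample, float(library_size)), stats
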