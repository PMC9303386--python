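"""Feature-anchored signal aggregation: TSS heatmap matrices, mean
profiles, per-feature occupancy, and occupancy-expression correlation.

Reads are counted by their 5' base with no fragment-extension shift
(MNase mononucleosome fragments need none); signal is scaled to 10 million
mapped reads. Profiles are strand-oriented: minus-strand features are
reflected so that biological upstream is always on the left.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .alignio import AlignmentRecord
from .intervals import FeatureSet
from .quantify import NORM_TOTAL


def tss_profile(
    reads: Iterable[AlignmentRecord],
    genes: FeatureSet,
    library_size: float,
    flank: int = 2000,
    bin_size: int = 50,
    norm_total: float = NORM_TOTAL,
) -> tuple[pd.DataFrame, pd.Series]:
    """Matrix of normalized read counts in fixed bins around each gene's
    TSS, plus the column-mean profile.

    Each read's 5' base is assigned to a bin by its strand-oriented offset
    from the TSS (negative = upstream). Returns ``(matrix, mean_profile)``
    where the matrix rows are genes ordered by descending total signal and
    columns are labelled by the bin's left offset.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    n_bins = 2 * flank // bin_size
    gene_list = [g for g in genes if g.strand in ("+", "-")]
    index = {g.name: i for i, g in enumerate(gene_list)}
    mat = np.zeros((len(gene_list), n_bins))
    # anchor lookup: genes whose TSS window could contain a read position
    anchor = FeatureSet(genome=None)
    from .intervals import GenomicInterval

    for g in gene_list:
        lo = max(0, g.tss - flank)
        hi = g.tss + flank + 1
        anchor.add(GenomicInterval(g.chrom, lo, hi, g.strand, g.name, "other"))
    for read in reads:
        pos = read.five_prime
        for hit in anchor.overlapping(read.chrom, pos, pos + 1):
            g = gene_list[index[hit.name]]
            offset = pos - g.tss if g.strand == "+" else g.tss - pos
            if -flank <= offset < flank:
                mat[index[hit.name], (offset + flank) // bin_size] += 1
    mat *= norm_total / library_size
    cols = np.arange(-flank, flank, bin_size)
    df = pd.DataFrame(mat, index=[g.name for g in gene_list], columns=cols)
    df = df.loc[df.sum(axis=1).sort_values(ascending=False, kind="mergesort").index]
    mean_profile = pd.Series(mat.mean(axis=0), index=cols, name="mean")
    return df, mean_profile


def feature_occupancy(
    reads: Iterable[AlignmentRecord],
    features: FeatureSet,
    library_size: float,
    per_kb: bool = False,
    norm_total: float = NORM_TOTAL,
) -> pd.Series:
    """Normalized read count per feature (strand ignored — appropriate for
    ChIP signal), optionally per kilobase of feature length."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    counts = {f.name: 0.0 for f in features}
    for read in reads:
        hits: set[str] = set()
        for start, end in read.blocks:
            hits |= {f.name for f in features.overlapping(read.chrom, start, end)}
        for name in hits:
            counts[name] += 1
    out = pd.Series(counts, dtype=float) * (norm_total / library_size)
    if per_kb:
        lengths = pd.Series({f.name: len(f) / 1000.0 for f in features})
        out = out / lengths
    return out


def occupancy_expression_correlation(
    occupancy: pd.Series,
    expression: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between per-cluster ChIP occupancy and
    expression, with a seeded permutation p-value.

    Ties are handled exactly (average ranks). The p-value is
    ``(1 + #{|rho_perm| >= |rho_obs|}) / (n + 1)``, two-sided.
    """
    common = occupancy.index.intersection(expression.index)
    if len(common) < 5:
        raise ValueError("need at least 5 shared clusters")
    x = occupancy.loc[common].to_numpy(dtype=float)
    y = expression.loc[common].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return rho, p
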