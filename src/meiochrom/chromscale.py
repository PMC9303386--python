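"""Chromosome-scale statistics: Manhattan-style window tables,
per-chromosome means, and sex-vs-autosome fold enrichment.

Summaries use full windows only (terminal partial windows are excluded so
per-window means stay comparable), and the sex/autosome pools weight
chromosomes by their full-window counts — a read-density interpretation of
pooled Manhattan quantification. Per-chromosome means are also reported so
either view is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeModel
from .quantify import WindowCoverage


@dataclass
class EnrichmentSummary:
    """Per-chromosome and pooled window-coverage means with the
    sex-vs-autosome fold enrichment."""

    per_chromosome: pd.Series  # mean normalized coverage per chromosome
    autosome_mean: float
    sex_mean: float
    fold_enrichment: float  # sex mean / autosome mean
    input_corrected_fold: float | None = None
    missing_chromosomes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "per_chromosome": {k: float(v) for k, v in self.per_chromosome.items()},
            "autosome_mean": self.autosome_mean,
            "sex_mean": self.sex_mean,
            "fold_enrichment": self.fold_enrichment,
            "missing_chromosomes": list(self.missing_chromosomes),
        }
        if self.input_corrected_fold is not None:
            d["input_corrected_fold"] = self.input_corrected_fold
        return d


def _pooled_means(cov: WindowCoverage, genome: GenomeModel):
    full = cov.table[~cov.table["partial"].astype(bool)]
    per_chrom = full.groupby("chrom")["norm"].mean()
    missing = tuple(c for c, _ in genome if c not in per_chrom.index)
    auto = full[full["chrom"].isin(genome.autosomes)]["norm"]
    sex = full[full["chrom"].isin(genome.sex_chromosomes)]["norm"]
    per_chrom = per_chrom.reindex([c for c, _ in genome if c in per_chrom.index])
    return per_chrom, float(auto.mean()), float(sex.mean()), missing


def chromosome_summary(
    cov: WindowCoverage,
    genome: GenomeModel,
    input_cov: WindowCoverage | None = None,
) -> EnrichmentSummary:
    """Per-chromosome mean normalized window coverage and the pooled
    sex/autosome fold enrichment.

    Pooled means are computed over all full windows of each class (i.e.
    weighted by window counts). With an input-control coverage the
    input-corrected fold (IP_sex/IP_auto) / (input_sex/input_auto) is also
    reported.
    """
    per_chrom, auto_mean, sex_mean, missing = _pooled_means(cov, genome)
    if auto_mean <= 0:
        raise ValueError("autosome mean is zero; fold enrichment undefined")
    fold = sex_mean / auto_mean
    corrected = None
    if input_cov is not None:
        _, in_auto, in_sex, _ = _pooled_means(input_cov, genome)
        if in_auto > 0 and in_sex > 0:
            corrected = fold / (in_sex / in_auto)
    return EnrichmentSummary(
        per_chromosome=per_chrom,
        autosome_mean=auto_mean,
        sex_mean=sex_mean,
        fold_enrichment=fold,
        input_corrected_fold=corrected,
        missing_chromosomes=missing,
    )


def manhattan_table(covs: list[WindowCoverage], genome: GenomeModel) -> pd.DataFrame:
    """Long-format (sample, chrom, start, norm) table in genome order,
    suitable for Manhattan-style plotting."""
    chrom_order = {c: i for i, (c, _) in enumerate(genome)}
    frames = []
    for cov in covs:
        bad = set(cov.table["chrom"]) - set(chrom_order)
        if bad:
            raise ValueError(f"coverage on chromosomes outside genome: {sorted(bad)}")
        df = cov.table[["chrom", "start", "norm", "partial"]].copy()
        df.insert(0, "sample", cov.sample)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["_order"] = out["chrom"].map(chrom_order)
    out = out.sort_values(["sample", "_order", "start"], kind="mergesort")
    return out.drop(columns="_order").reset_index(drop=True)


def windowed_expression_change(
    cov_a: WindowCoverage,
    cov_b: WindowCoverage,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-window log2((B + c) / (A + c)) on normalized coverage, plus the
    per-chromosome median log-ratio (the directionality statistic).

    The pseudocount ``c`` (default 1 normalized read) bounds ratios at
    empty windows. The directionality median is taken over full windows
    with coverage in at least one sample — windows empty in both carry no
    directional information. Both coverages must share a window grid.
    """
    a, b = cov_a.table, cov_b.table
    if not (a["chrom"].equals(b["chrom"]) and a["start"].equals(b["start"])):
        raise ValueError("window grids differ between samples")
    an = a["norm"].to_numpy()
    bn = b["norm"].to_numpy()
    ratio = np.log2((bn + pseudocount) / (an + pseudocount))
    out = a[["chrom", "start", "end", "partial"]].copy()
    out["log2_ratio"] = ratio
    out["expressed"] = (an + bn) > 0
    full = out[~out["partial"].astype(bool) & out["expressed"]]
    medians = full.groupby("chrom")["log2_ratio"].median()
    return out, medians


def plot_manhattan(table: pd.DataFrame, genome: GenomeModel, path) -> None:
    """Render a per-chromosome Manhattan scatter of normalized window
    coverage (one panel per sample)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = table["sample"].unique()
    fig, axes = plt.subplots(len(samples), 1, figsize=(10, 2.2 * len(samples)), squeeze=False)
    offsets, cum = {}, 0
    for chrom, length in genome:
        offsets[chrom] = cum
        cum += length
    for ax, sample in zip(axes[:, 0], samples):
        sub = table[table["sample"] == sample]
        xs = sub["chrom"].map(offsets) + sub["start"]
        colors = ["tab:red" if c in genome.sex_chromosomes else "tab:gray" for c in sub["chrom"]]
        ax.scatter(xs, sub["norm"], s=3, c=colors)
        ax.set_ylabel(sample, fontsize=8)
    axes[-1, 0].set_xlabel("genome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
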