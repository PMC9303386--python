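"""Dataset layout and the four analysis stage chains.

A dataset directory (as written by ``meiochrom simulate``) contains::

    chrom.sizes             genome (TSV: name, length)
    sex_chromosomes.txt     one name per line
    genes.gtf               gene annotation with gene_id / gene_biotype
    pirna_clusters.bed      BED6 cluster intervals
    repeats.bed             BED6 repeat instances (name = family/instance)
    samples.tsv             sample sheet
    rnaseq/<sample>.sam     stranded RNA-seq alignments
    chip/<track>_<stage>.sam   ChIP IP and input alignments
    truth/                  planted truth tables (when simulated)
    manifest.json           seed + sha256 checksums

Each ``run_*`` function executes one stage chain and writes TSV/JSON
results plus a log of every filter decision, so the conservation
invariants are auditable from the logs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromscale, differential, metaprofile, quantify
from .alignio import read_alignments
from .config import PipelineConfig
from .intervals import FeatureSet, GenomeModel, build_mask, make_windows
from .quantify import CountTable, WindowCoverage, window_coverage
from .simulate import Annotation, SimulationConfig, simulate_annotation, simulate_chipseq, simulate_rnaseq, write_sam

STAGES = ("meiotic", "postmeiotic")


# ---------------------------------------------------------------------------
# simulate → dataset directory


def write_dataset(config: SimulationConfig, outdir, force: bool = False) -> Path:
    """Simulate a full dataset and write it under ``outdir``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    (outdir / "rnaseq").mkdir(parents=True, exist_ok=True)
    (outdir / "chip").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    ann = simulate_annotation(config)
    genome = ann.genome
    genome.to_chrom_sizes(outdir / "chrom.sizes")
    (outdir / "sex_chromosomes.txt").write_text(
        "".join(f"{c}\n" for c in sorted(genome.sex_chromosomes))
    )
    ann.genes.to_gtf(outdir / "genes.gtf")
    ann.clusters.to_bed6(outdir / "pirna_clusters.bed")
    ann.repeats.to_bed6(outdir / "repeats.bed")

    reads_by_sample, truth_counts = simulate_rnaseq(config, ann)
    for sample, reads in reads_by_sample.items():
        write_sam(reads, genome, outdir / "rnaseq" / f"{sample}.sam")
    truth_counts.counts.to_csv(outdir / "truth" / "counts.tsv", sep="\t", index_label="feature")
    truth_counts.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    ann.truth.to_tsv(outdir / "truth" / "features.tsv", outdir / "truth" / "windows.tsv")

    for stage in STAGES:
        tracks = simulate_chipseq(config, ann, stage)
        for name, reads in tracks.items():
            write_sam(reads, genome, outdir / "chip" / f"{name}.sam")

    manifest = {
        "seed": config.seed,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# dataset loading


@dataclass
class Dataset:
    root: Path
    genome: GenomeModel
    genes: FeatureSet
    clusters: FeatureSet
    repeats: FeatureSet
    samples: pd.DataFrame

    @classmethod
    def load(cls, root) -> "Dataset":
        root = Path(root)
        for required in ("chrom.sizes", "genes.gtf", "samples.tsv"):
            if not (root / required).exists():
                raise FileNotFoundError(f"missing input file: {root / required}")
        sex = []
        if (root / "sex_chromosomes.txt").exists():
            sex = (root / "sex_chromosomes.txt").read_text().split()
        genome = GenomeModel.from_chrom_sizes(root / "chrom.sizes", sex)
        genes = FeatureSet.from_gtf(root / "genes.gtf", genome)
        clusters = (
            FeatureSet.from_bed6(root / "pirna_clusters.bed", genome, "pirna_cluster")
            if (root / "pirna_clusters.bed").exists()
            else FeatureSet(genome=genome)
        )
        repeats = (
            FeatureSet.from_bed6(root / "repeats.bed", genome, "repeat", name_is_family=True)
            if (root / "repeats.bed").exists()
            else FeatureSet(genome=genome)
        )
        samples = pd.read_csv(root / "samples.tsv", sep="\t", index_col="sample")
        return cls(root, genome, genes, clusters, repeats, samples)

    def rnaseq_reads(self, sample: str):
        return read_alignments(self.root / "rnaseq" / f"{sample}.sam", self.genome)

    def chip_reads(self, track: str, stage: str):
        return read_alignments(self.root / "chip" / f"{track}_{stage}.sam", self.genome)

    def stage_samples(self, stage: str) -> pd.DataFrame:
        return self.samples[self.samples["stage"] == stage]


def _log(outdir: Path, name: str, payload: dict) -> None:
    path = outdir / f"{name}.log.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=int))


# ---------------------------------------------------------------------------
# analysis stage chains


def run_genes(ds: Dataset, cfg: PipelineConfig, outdir) -> dict[str, differential.DEResult]:
    """Gene-level counting and KO-vs-WT testing within each stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols, stats = {}, {}
    from .alignio import filter_reads

    for sample in ds.samples.index:
        reads, fstats = filter_reads(ds.rnaseq_reads(sample), require_unique=True)
        cols[sample], cstats = quantify.count_gene_sample(reads, ds.genes, "opposite")
        stats[sample] = {"filter": fstats.as_dict(), "assignment": cstats}
    table = CountTable(pd.DataFrame(cols), ds.samples)
    table.to_tsv(outdir / "counts_genes.tsv")
    _log(outdir, "genes", stats)
    results = {}
    for stage in sorted(ds.samples["stage"].unique()):
        sub = table.subset_samples(list(ds.stage_samples(stage).index))
        res = differential.run_de_pipeline(
            sub, ("condition", "KO", "WT"), alpha=cfg.alpha, lfc_threshold=cfg.lfc_genes
        )
        res.to_tsv(outdir / f"de_genes_{stage}.tsv")
        results[stage] = res
    # meiotic -> post-meiotic transition within WT
    wt = ds.samples[ds.samples["condition"] == "WT"]
    if len(wt) >= 4 and wt["stage"].nunique() == 2:
        sub = table.subset_samples(list(wt.index))
        res = differential.run_de_pipeline(
            sub,
            ("stage", "postmeiotic", "meiotic"),
            alpha=cfg.alpha,
            lfc_threshold=cfg.lfc_genes,
        )
        res.to_tsv(outdir / "de_genes_transition_WT.tsv")
        results["transition_WT"] = res
    return results


def run_pirna(ds: Dataset, cfg: PipelineConfig, outdir) -> dict[str, differential.DEResult]:
    """piRNA cluster chain: genic masking, three-rule read filtering,
    opposite-strand counting, pooled gene+piRNA testing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = build_mask(
        ds.genes,
        ds.genome,
        biotypes=set(cfg.mask_biotypes),
        upstream=cfg.upstream,
        downstream=cfg.downstream,
    )
    pir_cols, gene_cols, stats = {}, {}, {}
    from .alignio import filter_reads

    for sample in ds.samples.index:
        reads = list(ds.rnaseq_reads(sample))
        pir_cols[sample], pstats = quantify.count_pirna_sample(reads, ds.clusters, mask)
        ureads, _ = filter_reads(reads, require_unique=True)
        gene_cols[sample], _ = quantify.count_gene_sample(ureads, ds.genes, "opposite")
        stats[sample] = pstats
    pir_table = CountTable(pd.DataFrame(pir_cols), ds.samples)
    gene_table = CountTable(pd.DataFrame(gene_cols), ds.samples)
    pir_table.to_tsv(outdir / "counts_pirna.tsv")
    _log(outdir, "pirna", stats)
    results = {}
    for stage in sorted(ds.samples["stage"].unique()):
        ids = list(ds.stage_samples(stage).index)
        res = differential.pooled_pirna_test(
            gene_table.subset_samples(ids),
            pir_table.subset_samples(ids),
            ("condition", "KO", "WT"),
            alpha=cfg.alpha,
            lfc_threshold=cfg.lfc_pirna,
        )
        res.to_tsv(outdir / f"de_pirna_{stage}.tsv")
        results[stage] = res
    # meiotic -> post-meiotic transition within WT (the massive piRNA
    # repression readout)
    wt = ds.samples[ds.samples["condition"] == "WT"]
    if len(wt) >= 4 and wt["stage"].nunique() == 2:
        ids = list(wt.index)
        res = differential.pooled_pirna_test(
            gene_table.subset_samples(ids),
            pir_table.subset_samples(ids),
            ("stage", "postmeiotic", "meiotic"),
            alpha=cfg.alpha,
            lfc_threshold=cfg.lfc_pirna,
        )
        res.to_tsv(outdir / "de_pirna_transition_WT.tsv")
        results["transition_WT"] = res
    return results


def run_repeats(ds: Dataset, cfg: PipelineConfig, outdir) -> dict[str, differential.DEResult]:
    """Repeat-family chain: family counting, RPM floor, NB testing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols, stats = {}, {}
    from .alignio import filter_reads

    for sample in ds.samples.index:
        reads, fstats = filter_reads(ds.rnaseq_reads(sample), require_unique=True)
        cols[sample], cstats = quantify.count_repeat_sample(reads, ds.repeats)
        stats[sample] = {"filter": fstats.as_dict(), "assignment": cstats}
    table = CountTable(pd.DataFrame(cols), ds.samples)
    table.to_tsv(outdir / "counts_repeats.tsv")
    kept, excluded = quantify.rpm_filter(table, floor=cfg.rpm_floor)
    (outdir / "excluded_families.txt").write_text("".join(f"{f}\n" for f in excluded))
    _log(outdir, "repeats", stats)
    results = {}
    for stage in sorted(ds.samples["stage"].unique()):
        sub = kept.subset_samples(list(ds.stage_samples(stage).index))
        res = differential.run_de_pipeline(
            sub,
            ("condition", "KO", "WT"),
            alpha=cfg.alpha,
            lfc_threshold=cfg.lfc_repeats,
            independent_filtering=False,
        )
        res.to_tsv(outdir / f"de_repeats_{stage}.tsv")
        results[stage] = res
    return results


def run_chromscale(ds: Dataset, cfg: PipelineConfig, outdir) -> dict:
    """Chromosome-scale chain: 40 kb window coverage for ChIP IP vs input
    (sex-vs-autosome enrichment) and the per-chromosome RNA directionality
    medians (KO vs WT)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = make_windows(ds.genome, cfg.window)
    out: dict = {"chip": {}, "rna_direction": {}}
    for stage in STAGES:
        covs = {}
        for track in ("IP", "input"):
            path = ds.root / "chip" / f"{track}_{stage}.sam"
            if not path.exists():
                continue
            reads = list(ds.chip_reads(track, stage))
            lib = sum(1 for r in reads if r.unique)
            cov, wstats = window_coverage(
                (r for r in reads if r.unique), windows, lib, f"{track}_{stage}", cfg.norm_total
            )
            cov.to_tsv(outdir / f"coverage_{track}_{stage}.tsv")
            cov.to_bedgraph(outdir / f"coverage_{track}_{stage}.bedgraph")
            covs[track] = cov
        if "IP" in covs:
            summary = chromscale.chromosome_summary(covs["IP"], ds.genome, covs.get("input"))
            out["chip"][stage] = summary.as_dict()
    # RNA directionality: replicate-pooled coverage per condition
    for stage in sorted(ds.samples["stage"].unique()):
        sheet = ds.stage_samples(stage)
        covs = {}
        for cond in ("WT", "KO"):
            ids = sheet[sheet["condition"] == cond].index
            reads = []
            for sample in ids:
                from .alignio import filter_reads

                kept, _ = filter_reads(ds.rnaseq_reads(sample), require_unique=True)
                reads.extend(kept)
            covs[cond], _ = window_coverage(
                reads, windows, max(len(reads), 1), f"{cond}_{stage}", cfg.norm_total
            )
        table, medians = chromscale.windowed_expression_change(covs["WT"], covs["KO"])
        table.to_csv(outdir / f"rna_log2_ratio_{stage}.tsv", sep="\t", index=False)
        medians.to_csv(outdir / f"rna_direction_medians_{stage}.tsv", sep="\t")
        out["rna_direction"][stage] = {k: float(v) for k, v in medians.items()}
    (outdir / "chromscale.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return out


def run_profile(ds: Dataset, cfg: PipelineConfig, outdir) -> dict:
    """TSS metaprofiles of the ChIP IP signal and the piRNA-cluster
    occupancy-expression correlation, per stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    mask = build_mask(
        ds.genes,
        ds.genome,
        biotypes=set(cfg.mask_biotypes),
        upstream=cfg.upstream,
        downstream=cfg.downstream,
    )
    for stage in STAGES:
        path = ds.root / "chip" / f"IP_{stage}.sam"
        if not path.exists():
            continue
        reads = [r for r in ds.chip_reads("IP", stage) if r.unique]
        lib = len(reads)
        matrix, mean_profile = metaprofile.tss_profile(
            reads, ds.genes, lib, cfg.flank, cfg.bin_size, cfg.norm_total
        )
        matrix.to_csv(outdir / f"tss_matrix_{stage}.tsv", sep="\t", index_label="feature")
        mean_profile.to_csv(outdir / f"tss_profile_{stage}.tsv", sep="\t", index_label="offset")
        occupancy = metaprofile.feature_occupancy(reads, ds.clusters, lib, per_kb=True)
        occupancy.to_csv(outdir / f"cluster_occupancy_{stage}.tsv", sep="\t", header=["per_kb"])
        stage_info = {
            "peak_offsets": _profile_peaks(mean_profile, cfg.bin_size),
        }
        # expression of clusters in matching WT samples
        expr = _cluster_expression(ds, cfg, mask, stage)
        if expr is not None and len(expr) >= 5 and occupancy.nunique() > 1 and expr.nunique() > 1:
            rho, p = metaprofile.occupancy_expression_correlation(
                occupancy, expr, seed=cfg.seed
            )
            stage_info["occupancy_expression_rho"] = rho
            stage_info["occupancy_expression_p"] = p
        out[stage] = stage_info
    (outdir / "profile.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return out


def _profile_peaks(mean_profile: pd.Series, bin_size: int) -> list[int]:
    """Centers (bp offsets) of the two largest local maxima."""
    v = mean_profile.to_numpy()
    offs = mean_profile.index.to_numpy()
    peaks = [
        i
        for i in range(1, len(v) - 1)
        if v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] > 0
    ]
    peaks.sort(key=lambda i: -v[i])
    return sorted(int(offs[i]) + bin_size // 2 for i in peaks[:2])


def _cluster_expression(ds, cfg, mask, stage):
    sheet = ds.stage_samples(stage)
    ids = sheet[sheet["condition"] == "WT"].index
    if len(ids) == 0:
        return None
    total = None
    for sample in ids:
        counts, _ = quantify.count_pirna_sample(list(ds.rnaseq_reads(sample)), ds.clusters, mask)
        total = counts if total is None else total + counts
    return total


ANALYSES = {
    "genes": run_genes,
    "pirna": run_pirna,
    "repeats": run_repeats,
    "chromscale": run_chromscale,
    "profile": run_profile,
}


# ---------------------------------------------------------------------------
# report


def build_report(results_dir) -> dict:
    """Assemble the machine-readable summary from whatever result tables
    are present; missing sections are marked, not fatal."""
    results_dir = Path(results_dir)
    report: dict = {"sections": {}}
    de_section = {}
    for path in sorted(results_dir.rglob("de_*.tsv")):
        df = pd.read_csv(path, sep="\t", index_col="feature")
        sig = df[df["significant"].fillna(False).astype(bool)]
        de_section[path.stem] = {
            "n_features": int(len(df)),
            "n_significant": int(len(sig)),
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }
    report["sections"]["differential"] = de_section or {"missing": True}
    chrom_path = next(iter(sorted(results_dir.rglob("chromscale.json"))), None)
    report["sections"]["chromscale"] = (
        json.loads(chrom_path.read_text()) if chrom_path else {"missing": True}
    )
    prof_path = next(iter(sorted(results_dir.rglob("profile.json"))), None)
    report["sections"]["profile"] = (
        json.loads(prof_path.read_text()) if prof_path else {"missing": True}
    )
    return report


def report_text(report: dict) -> str:
    lines = ["meiochrom analysis report", "=" * 30]
    de = report["sections"].get("differential", {})
    if de.get("missing"):
        lines.append("differential: MISSING")
    else:
        for name, d in de.items():
            lines.append(
                f"{name}: {d['n_significant']} significant "
                f"({d['n_up']} up, {d['n_down']} down) of {d['n_features']}"
            )
    chrom = report["sections"].get("chromscale", {})
    if chrom.get("missing"):
        lines.append("chromscale: MISSING")
    else:
        for stage, d in chrom.get("chip", {}).items():
            lines.append(
                f"ChIP {stage}: sex/autosome fold enrichment "
                f"{d['fold_enrichment']:.2f}"
            )
        for stage, med in chrom.get("rna_direction", {}).items():
            parts = ", ".join(f"{c}={v:+.2f}" for c, v in med.items())
            lines.append(f"RNA direction medians {stage}: {parts}")
    prof = report["sections"].get("profile", {})
    if prof.get("missing"):
        lines.append("profile: MISSING")
    else:
        for stage, d in prof.items():
            lines.append(f"TSS peaks {stage}: {d.get('peak_offsets')}")
            if "occupancy_expression_rho" in d:
                lines.append(
                    f"occupancy~expression {stage}: rho="
                    f"{d['occupancy_expression_rho']:.3f} p={d['occupancy_expression_p']:.2g}"
                )
    return "\n".join(lines) + "\n"
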