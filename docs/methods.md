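# Methods

This note documents the models, conventions and numerical choices behind
`meiochrom`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted at parse time, and abutting intervals never
overlap. The TSS of a stranded interval is its 5' end (`start` on `+`,
`end - 1` on `-`); the TES is the symmetric 3' end. Extension of a gene by
`upstream` bp before the TSS and `downstream` bp past the TES is therefore
`[start - upstream, end + downstream)` on the plus strand and
`[start - downstream, end + upstream)` on the minus strand, clamped to the
chromosome.

Stranded RNA-seq follows the dUTP/first-strand chemistry: the sequenced
read is **antisense** to its transcript. Consequently every transcript-
aware overlap test in the package (genic masking, gene counting, cluster
assignment) uses *opposite-strand* overlap between read and feature.

## piRNA cluster quantification

Reads are filtered in three steps before cluster counting:

1. non-unique alignments removed (hit-count tag `NH == 1` preferred;
   MAPQ ≥ 30 as a documented fallback for aligners without the tag);
2. split-mapped reads (alignments with a skipped-region gap) removed —
   spliced artifacts, not precursor signal. Deletions do **not** split a
   read's blocks; only `N` operators do;
3. reads overlapping, on the opposite strand, any gene of the masked
   biotypes (IG_C/D/J/V genes, Mt_rRNA, Mt_tRNA, polymorphic pseudogene,
   protein_coding, pseudogene, rRNA) extended 3 kb / 10 kb removed — this
   absorbs polymerase read-through from genic transcription.

Mask intervals are merged per strand (strand must survive merging because
the downstream overlap test is strand-aware; merging itself does not change
which reads are removed). Surviving reads are assigned to clusters by
opposite-strand, ≥ 1 bp block overlap; a read overlapping several clusters
counts in each by default (clusters rarely overlap; single-assignment is
available by flag).

## Gene and repeat counting

Gene counting re-implements union-mode semantics: a read is assigned to a
gene only when every aligned block overlaps that gene under the strand mode
and no other gene overlaps the read at all; reads touching two genes are
dropped as ambiguous and audited. The split-read filter is **off** for gene
counting and **on** for piRNA counting by default (exposed as a flag).

Repeat counting is family-level: a read counts for family F when any block
overlaps any instance of F. Strand is ignored by default — repeat families
contain instances in both orientations. A read overlapping instances of two
families counts in both (documented multi-assignment). Families below a
5 RPM floor (reads per million mapped) are excluded; the default excludes a
family only when **all** samples are below the floor, the stricter
any-sample reading is a flag.

Every counting stage returns assignment statistics satisfying
`assigned + dropped = input`, so conservation is auditable from logs.

## Window coverage and chromosome-scale enrichment

Chromosomes are tiled with non-overlapping 40 kb windows; a terminal window
shorter than 40 kb is kept but flagged partial, and all chromosome-level
summaries use full windows only (equal-length comparability). Each read is
assigned to the single window containing its 5'-most base — windows are
three orders of magnitude wider than reads, so the difference from
fractional assignment is negligible while conservation stays exact.
Coverage is normalized to 10 million mapped reads.

The sex-vs-autosome fold enrichment is the ratio of pooled mean normalized
coverage, where pooling weights chromosomes by their full-window counts (a
read-density view of the pooled Manhattan quantification); per-chromosome
means are reported alongside so the equal-weight view is recoverable. With
an input control, the input-corrected fold
(IP_sex/IP_auto)/(input_sex/input_auto) is also emitted, since raw and
corrected versions answer slightly different questions.

Windowed expression directionality is log2((B + c)/(A + c)) per window on
normalized coverage with pseudocount c = 1 normalized read; the
per-chromosome median is taken over full windows expressed in at least one
sample — windows empty in both carry no directional information and would
otherwise drag medians to zero on sparse miniature genomes.

## TSS metaprofiles

Each read's 5' base is binned by its strand-oriented offset from the gene
TSS (upstream always left; minus-strand genes reflected), over ±2 kb in
50 bp bins by default, scaled to 10 million reads. No fragment-extension
shift is applied (MNase mononucleosome fragments need none); the shift is
a parameter. Heatmap rows are ordered by descending total signal — a
deterministic ordering, in place of k-means clustering, which is a
non-goal. The occupancy–expression relation uses Spearman rank correlation
with average-rank tie handling and a seeded two-sided permutation p-value
(10⁴ permutations, `p = (1 + #{|ρ*| ≥ |ρ|}) / (n + 1)`).

## Negative-binomial differential pipeline

The count model is K_ij ~ NB(μ_ij, α_i) with Var = μ + αμ² and
μ_ij = s_j q_i 2^(β_i x_j), x_j the group indicator. Contrast orientation
is fixed KO − WT and post-meiotic − meiotic.

* **Size factors** — median over features (with positive geometric mean)
  of k_ij / geometric-mean_i; no rescaling is applied, so factors are
  defined up to a common constant (only ratios matter in the GLM offset).
* **Dispersion** — per-feature maximization of the Cox–Reid-adjusted
  profile likelihood (the −½ log det(XᵀWX) term corrects the downward bias
  of the MLE at few replicates), by vectorized golden-section search on
  log α over [10⁻⁸, 20]. A trend α(μ) = a₁/μ + a₀ is fitted to the
  per-feature estimates by least squares with one outlier-trimming round;
  estimates are then shrunk toward the trend by maximizing the
  CR-likelihood plus a log-normal prior centered on the trend. The prior
  variance is data-driven: the squared MAD of log residuals minus the
  expected sampling variance trigamma((m−p)/2), floored at 0.25. All-zero
  features are flagged and excluded from testing.
* **Wald test** — IRLS on the two-column design [1, x] with offset log s_j
  (closed-form 2×2 solve, vectorized across features), deviance tolerance
  10⁻⁸, at most 100 iterations, coefficients clipped at |β| ≤ 30 (natural
  log); non-converged features get missing p-values. SE from the observed
  Fisher information; β̂/SE against a standard normal, two-sided.
* **Cook's distance** — D = r²_Pearson/p · h/(1−h)², computed with the
  **trend** dispersion rather than the per-feature estimate: a single
  outlying count inflates its own gene-wise dispersion enough to mask
  itself, and the trend reflects what similar-abundance features do. A
  feature is flagged when max_j D exceeds the 0.99 quantile of F(p, m−p);
  the filter is disabled when any group has fewer than 3 replicates, so it
  is inert on the 2+2 study design and active on larger synthetic designs.
* **Independent filtering** — scan baseMean-quantile cutoffs
  θ ∈ {0, 0.01, …, 0.95}; BH-adjust the passing features at each θ and
  keep the θ maximizing rejections at the target α (smallest θ on ties;
  the scan is deterministic). Filtered features get missing padj.
* **BH adjustment** — padj_(i) = min_{j≥i} (m·p_(j)/j) capped at 1;
  missing p-values are excluded from m.
* **Pooled piRNA testing** — cluster counts are row-concatenated with gene
  counts; size factors, dispersions, test and adjustment all run on the
  pooled table, and results are reported for cluster rows at padj < 0.01,
  |log2FC| > 0.5. Pooling anchors normalization to the stable gene
  background, so a genuine global piRNA shift is estimated rather than
  normalized away.

This pipeline is a deliberately simplified analogue of the DESeq2 family
of methods: gene-wise MAP dispersion with trend shrinkage and a Wald test,
but no LFC shrinkage, no zero-count outlier replacement and no claim of
numeric identity with any DESeq2 version. It is validated by simulation
properties (type-I control, power/FDP on planted effects, parameter
recovery), not by matching another implementation bit for bit.

## The synthetic-data generator

The generator emulates the study design the package targets: 2 conditions
(WT, KO) × 2 stages (meiotic, post-meiotic) × 2 replicates; single-end
50 nt reads; first-strand orientation (every non-contaminant read is
antisense to its feature); NB counts with α = 0.05 by default.

Defaults (the planted conditions):

* miniature genome of five 3 Mb autosomes, a 2 Mb chrX and a 0.8 Mb chrY;
* 300 non-overlapping genes with biotypes drawn from the masked list plus
  lincRNA/miRNA (which exercise biotype filtering); sex-linked genes get
  ~15% of the autosomal baseline expression (meiotic sex-chromosome
  inactivation) and a planted +1.5 log2FC in the KO; a handful of
  autosomal genes at ±2;
* 101 piRNA clusters (15–40 kb), 20% placed on the same strand directly
  downstream of a maskable gene — inside its 3 kb/10 kb masking reach, so
  the genic mask is exercised — and the rest kept > 13 kb from any gene;
  35 clusters planted at −0.415 (≈25% decrease) in the KO and 88 planted
  at −3.32 (≈10-fold down) across the stage transition;
* 12 repeat families × 30 instances, including RLTR10B and RLTR10B2
  planted +1.5 in the KO;
* contaminants: 2% split-mapped reads (two 25 nt blocks, 100 bp gap,
  placed inside clusters — the artifact class the split filter exists
  for) and 3% non-unique reads (NH = 2) placed uniformly;
* ChIP: input uniform over the genome; IP with a ×4 multiplier on sex-
  chromosome windows, 15% of reads drawn from a bimodal TSS kernel (two
  Gaussians at ±500 bp, SD 150 bp, per-gene intensity carrying the sex
  multiplier so the window-level fold is preserved), and 5% placed over
  clusters proportional to planted cluster expression.

Library depth is a free parameter (deposited-study depths are not part of
the model); the default 200,000 reads per sample on the ~18 Mb miniature
genome gives per-feature coverage comparable to tens of millions of reads
on a mammalian genome. The test suite and the acceptance script use the
same design at reduced sizes (a `miniature` configuration: 5 chromosomes,
120 genes, 40 clusters, 40,000 reads/sample) — the package's own choice of
benchmark scale; determinism and all planted-effect recoveries are scale-
free properties.

Feature placement is by rejection-free carving of per-chromosome free
segments (weighted random segment choice, then uniform offset). Requested
features that cannot fit raise a packing error; nothing is silently
truncated. Identical (seed, config) give byte-identical outputs, including
SAM files.

What the generator does **not** emulate: nucleotide sequences and base
qualities (reads are coordinate-level), mappability structure, PCR
duplicates, fragment-length variation, GC and accessibility biases,
isoform structure, and aligner-specific artifacts beyond the two
contaminant classes. Passing recovery tests therefore demonstrates the
correctness of the counting/statistics chain under the stated model — not
robustness to every artifact of real libraries.

## Count-level benchmark scenarios

Statistical guarantees are benchmarked at the count level (no read
simulation needed): an all-null 2+2 design with 5,000 NB features for the
false-positive rate; and the pooled scenario of 101 clusters — 88 planted
~10-fold down — against 2,000 stable genes for sensitivity and false
discovery proportion at the piRNA thresholds. At two replicates a 25%
decrease is below the detection floor, and the pipeline correctly calls
nothing for it; the detectable planted effects are the ten-fold ones.

## Known limitations

* One two-level factor per comparison; no multi-factor designs, no
  likelihood-ratio tests, no LFC shrinkage estimators.
* Interval queries use an interval tree per chromosome — appropriate for
  annotation-scale feature sets (10²–10⁵ intervals), not optimized for
  hundreds of millions of reads.
* The Manhattan/profile plotting helpers are minimal; figure-perfect
  rendering is out of scope.
* DIP-seq (DNA methylation) interpretation, peak calling, liftOver
  conversion and functional-annotation clustering are non-goals.
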