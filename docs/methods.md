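# Methods

## The assay model

HELP interrogates cytosine methylation by comparing two digests of the
same DNA: HpaII cuts only unmethylated CCGG sites, MspI cuts
regardless of methylation. Fragments between two HpaII sites 200–2,000
bp apart (HpaII-amplifiable fragments, HAFs) amplify in the HpaII
channel only when unmethylated, so after co-hybridization on a
two-channel array the per-fragment log₂(HpaII/MspI) ratio is a
monotone *decreasing* readout of methylation. The package treats each
HAF as the unit locus throughout; adjacent fragments are never merged.

## Processing

**Summarization.** Each fragment's channel signal is the robust
trimmed mean of its probe intensities: sort, drop ⌊f·n⌋ values from
each tail (f = 0.25 by default, i.e. the common per-tail convention
for a "25% trimmed mean"), average the rest; the median is the
fallback in the degenerate case where trimming would empty the set.

**Background and status.** Dedicated random probes measure
hybridization background. The per-array threshold is
median + 2.5·MAD of the random-probe signals. MAD is implemented as
the *median* absolute deviation from the median (no 1.4826
consistency factor), with a configuration switch to the *mean*
absolute deviation, because "mean absolute differences" is ambiguous
between the two conventions and the median form is the standard
robust scale. Both channels' random probes are pooled per array since
background is channel-agnostic. Fragments with MspI at or below
threshold are *failed* (no PCR amplification — deletions, sequence
errors, experimental dropout); otherwise HpaII at or below threshold
means fully *methylated*; the rest are *amplifying* and enter the
continuous analysis. Loci failed in more than half the samples of
either clinical group are dropped before testing (the cross-sample
handling is otherwise undefined; this keeps the t-test's group sizes
honest). Zero intensities are floored at 10⁻⁶ before logs.

**Normalization.** Array-to-array intensity distortions in HELP data
are fragment-size dependent, so log ratios of amplifying fragments are
quantile-aligned across samples within sliding windows of size-sorted
fragments. Windows hold a fixed count (default 1,000 fragments,
density-adaptive by construction) and step by half a window; within a
window each sample's values are replaced by the across-sample mean of
order statistics at their rank (linear interpolation reconciles
samples contributing different numbers of finite values); fragments
covered by overlapping windows get the average. Within-sample ranks
are preserved inside each window, a single sample passes through
unchanged, and with one window the operation is the textbook quantile
normalization and is idempotent. Finally each array is centered to
zero mean over its amplifying entries; entries are labelled
*methylated* (centered ratio < 0) or *hypomethylated* (> 0).

## Differential methylation

Per locus, a pooled-variance two-sample t-test (df = n₁+n₂−2,
two-tailed) compares case vs control centered ratios; Welch's form is
available by flag but pooled is the classical default for an
unqualified two-sample t. Δ = mean(case) − mean(control); Δ > 0 means
hypomethylated in cases. DMRs satisfy P < 0.01 *and* effect > 0.5,
both strict; the effect filter defaults to the log₂ scale (|Δ| > 0.5,
i.e. "more than 50% difference" read on the scale actually tested),
with a flag for the raw-ratio reading |2^Δ − 1| > 0.5. Output is
ranked by |t|. No multiple-testing correction is applied at this stage
(the discovery filter operates on raw P); BH control appears only in
the expression module. For the heatmap view, loci at P < 1.5·10⁻⁴ and
|Δ| ≥ 0.5 are clustered with average-linkage agglomeration under
squared-Euclidean dissimilarity — only the dissimilarity is dictated
by the design; average linkage is this package's choice. Missing
entries are pairwise-excluded and the shared-coordinate sum of squares
is rescaled to full dimension. Volcano tables floor P = 0 (t-overflow)
at 10⁻³⁰⁰.

## Regulatory annotation

Coordinates are 0-based half-open everywhere (BED convention), one
assembly per run. RefSeq-style categories are exclusive with priority
promoter > 5′UTR > 3′UTR > TTS > exon > intron > intergenic, so small
regulatory categories are not swallowed by gene-body overlap. The
promoter window is TSS −1,000/+500 bp strand-aware and the TTS window
±500 bp — the category windows are not externally fixed, so they are
configurable and recorded in outputs. UTR calls require annotated
coding bounds; without them UTRs collapse into exon. The nearest gene
minimizes |fragment midpoint − TSS|, ties broken lexicographically.
Enrichment ratios divide the DMR category fraction by the whole-array
fraction. Chromatin-state overlap counts any state sharing ≥ 1 bp with
a DMR (a DMR spanning several segments counts once per state). DHS
enrichment compares the number of DMRs touching ≥ 1 peak against the
same statistic on permuted sets of random loci matched on count and
mean fragment size (fixed size = the mean, since only count and
average size are matched); chromosomes are sampled proportional to
length. The empirical p uses the add-one rule, (1 + #{null ≥ obs}) /
(B + 1): never 0, never above 1, and conservative on a discrete count.

## Expression integration

Genes whose larger group mean falls below the 20th percentile of all
pooled gene-level group means are excluded before testing (the
reference distribution for the percentile is the data itself — with
this definition at least 80% of genes always survive). The rest get
two-sample t-tests and BH step-up control at 0.05. Concordance
convention: hypomethylation in cases pairs with up-regulation in
cases. Replication concordance calls a gene confirmed when its
replication methylation difference is nonzero, significant (unadjusted
p < 0.05 whenever p-values are present; the rule is caller-supplied
because "concordant regulation" has no single operational definition),
and sign-matched (discovery hypo ↔ negative absolute difference).
Probes collapse to genes by largest |difference| — deterministic and
audit-friendly. The pipeline's reported concordance restricts the
denominator to genes actually present on the replication platform,
mirroring how validation cohorts are compared in practice; genes
absent from the platform are listed separately. Absolute-vs-relative
validation is a plain Pearson correlation on matched loci and is
expected negative.

## The synthetic generator

The generator emulates the observables of a 26-sample (12 control vs
14 case) HELP study:

* **Fragment map** — disjoint sorted HAFs on a small multi-chromosome
  genome; sizes follow a shifted exponential truncated to
  [200, 2,000] bp with scale 245, giving the right-skewed distribution
  and ~443 bp mean characteristic of DMR-scale HAF sets; exponential
  gaps (mean 600 bp) guarantee disjointness.
* **Truth** — exactly `n_dmr` fragments (default 500 of 10,000) get a
  case shift of magnitude ~N(1.0, 0.2) log₂ units; 70% hypomethylated
  by default. Control methylation fractions m ~ Beta(2,2) map to
  expected log ratios baseline − k·m (baseline 2.0, k 4.0) — a
  monotone decreasing link is all the assay semantics require. 2% of
  fragments are failed.
* **Intensities** — log-normal (multiplicative) noise: probe-level
  sd 0.2 log₂ units around channel means (MspI level 1,000 a.u.),
  plus a between-sample biological sd of 0.5 on the log ratio. Failed
  fragments and random probes draw *both* channels from a low
  log-normal background (median 50 a.u., sd 0.5), mirroring loci that
  did not amplify. Three probes per fragment (the real probe-per-
  fragment count is not fixed; 3 is configurable).
* **Annotation tracks** — half the fragments get covering refFlat-style
  gene models with exon/cds structure; a 10-label state segmentation
  tiles each chromosome with no gaps or overlaps; DHS peaks are placed
  inside planted DMR fragments with probability 0.3 (configurable; 0
  gives a null world), else uniformly.
* **Coupling** — DMR fragments map to nearest genes by the same
  nearest-TSS rule the annotation stage uses, so planted truth and
  recovered mapping agree; 40% of DMR genes get an expression shift of
  1.5 (sd 0.5 across samples), sign-concordant with probability 0.98.
  The replication table covers the mapped DMR genes with percent-scale
  differences sign-matched at probability 0.98; the paired
  absolute/relative table draws from the planted methylation fractions.

Every table has its own child stream of the master seed, so
regenerating one table never perturbs the others, and identical
configurations produce byte-identical files.

**What the generator does not emulate:** probe sequence content,
hybridization physics, dye bias, spatial chip artifacts, correlated
(regional) methylation along the genome, cell-type heterogeneity, or
bisulfite-platform error structure. Passing tests therefore establish
that the algorithms are implemented correctly and are calibrated under
idealized noise — not that the pipeline is robust to every failure
mode of physical arrays.

## Known behaviour at desk scale

The test suite plants 5% of loci as DMRs (500/10,000) to keep runs
fast; real HELP studies are ~25× sparser. At this density per-array
mean centering absorbs the net planted shift (~0.02 log₂ units),
slightly attenuating hypomethylation effects and strengthening
hypermethylation effects, and the called set includes a ~0.5-mix
false-positive tail. Both effects pull the *called-set* hypo fraction
a few points below the planted 70% (typically ~65%), while the
direction mix of the *recovered planted* DMRs stays at ~69–70%. At
realistic density the centering effect is negligible. The sensitivity
of the default configuration is ~90% per planted DMR.

## Problem sizes and numerical choices

Default test/acceptance runs use 10,000 fragments × 26 samples × 3
probes × 2 channels (~1.6M probe measurements), 999 permutations for
DHS enrichment, and complete in seconds to a few minutes. Tolerances:
column centering is exact to 10⁻⁹; oracle-equivalence checks are exact
to floating-point round-off; statistical checks use 3-sigma binomial
bands and, for p-value uniformity, the 1% Kolmogorov–Smirnov critical
value. Tie-breaks are deterministic everywhere (lexicographic gene
names, stable mergesort ordering), so identical seeds give identical
outputs.

## Limitations

* Each HAF is its own DMR; no merging of adjacent fragments.
* Raw expression preprocessing (CEL-level normalization) and
  bisulfite-array preprocessing are out of scope; the package consumes
  summarized matrices and difference tables.
* Peak calling, chromatin-state learning, motif analysis, and genome
  liftover are consumed as inputs, never produced.
* Physical chip quality control (spatial artifact detection) is not
  implemented.
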