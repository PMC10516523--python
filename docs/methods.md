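# Methods

This note documents the models, conventions, defaults, and numerical
choices behind `kaskit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and counting

All coordinates are 0-based half-open (BED convention) internally and in
every emitted file. Chromosome names match by exact string equality — no
"chr" aliasing — so an annotation/genome mismatch fails loudly. Single-end
tags shorter than 150 bp are extended to 150 bp from their 5′ end in the
strand direction (extension compensates for short reads; longer reads are
not truncated); properly paired mates are combined into one fragment
spanning min(start) to max(end).

Coverage uses read-count semantics: a tag counts once in every bin or
region it overlaps by ≥ 1 bp (not per-base coverage). RPKM for a region of
width *w* bp with *c* overlapping tags out of a library of *N* tags is
`c · 1e9 / (w · N)`; the library size is the number of deduplicated,
extended tags, fixed once per sample so that ratios are consistent across
modules.

Wherever a fold change would divide by a zero (or near-zero) density, the
denominator is floored at δ = the RPKM one single fragment would contribute
in that region for the relevant library. This guard is scale-aware and
deterministic, unlike an arbitrary epsilon.

## Shores

The local background of an element (peak or enhancer) is its two *shores*:
flanking regions of width equal to the element, immediately upstream and
downstream, clipped at chromosome bounds. A shore that retains less than
50% of its nominal width after clipping is unusable — a degenerate shore
makes density ratios unstable. Elements with one usable shore are scored on
that shore alone; with none, they are dropped (peaks) or labelled unusable
(enhancers). The same shore convention is used for the sharp-peak screen
and the enhancer comparison.

## QC metrics

FRiP is the fraction of tags overlapping the merged peak set. Complexity is
computed on raw (pre-deduplication) tags grouped by (chromosome, 5′
position, strand): NRF = distinct/total, PBC1 = single-read positions /
distinct, PBC2 = single-read / two-read positions (reported as an infinite
sentinel when no position is seen exactly twice — legitimate for small,
perfectly complex libraries). The fingerprint curve is the Lorenz curve of
raw counts in fixed 500 bp bins (a conventional desk-scale choice; the bin
size is a flag). Saturation re-computes FRiP on seeded without-replacement
subsamples against the fixed full-data peak set. Replicate correlation is
Pearson on log2(RPKM + 1) over a supplied region set; the transform and
region set are this package's documented choice. The verdict is `pass` iff
n_peaks ≥ 50 000 AND FRiP > 0.40 (strict), else `warn` — thresholds derive
from live human/mouse cell lines and are overridable flags, never a hard
failure.

## Peak integration

Sharp candidates (already q ≤ 0.01 and ≥ 1.5× vs Input from the upstream
caller) are re-screened: kept iff case density / max(Input density, δ) ≥ 5
AND case density / max(mean usable-shore case density, δ) ≥ 2. Broad peaks
are the subtraction of the accepted sharp peaks from the broad candidates;
fragments shorter than 150 bp (one read length) are discarded as not
meaningful broad signal. Feature annotation assigns each peak by midpoint
with priority promoter (TSS ± 2 kb) > terminator (TES → TES+3 kb,
strand-aware) > gene body > intergenic, which yields a clean partition
whose percentages sum to 100.

Note the two promoter conventions: ± 0.5 kb for the transcription indices,
± 2 kb for feature annotation — both are deliberate and exposed as separate
flags.

## Transcription indices

PI, EI, TI as in the README; promoter-proximal and gene-body densities are
computed independently (no masking of overlapping genes — indices are
defined per gene). Genes narrower than 1 kb are excluded with a reason code
(the ± 0.5 kb promoter would swallow the body). PI and TI are null when the
body density is zero; EI is always the arithmetic mean of promoter and body
densities. Tertiles split the non-null values at the empirical 1/3 and 2/3
quantiles with stable gene-name tie-breaking; if every value ties, all
genes land in the middle group with a warning.

## SST enhancer classification

An enhancer is SST iff (a) its mean per-bin density is ≥ 1.5× the pooled
mean of its two shores and (b) a one-way fixed-effects ANOVA across the
three groups of per-50 bp-bin RPKM values (enhancer, left shore, right
shore) gives p ≤ 0.05. Bins are the observational unit because no
biological replicates are assumed; this treats bins as exchangeable
replicates, which understates within-region autocorrelation (reads span
several bins), so the ANOVA p-value is optimistic in absolute terms — the
conjunction with the fold filter is what carries the specificity, and the
pass-through rejection rate is verified by simulation rather than assumed
from the nominal α. p-values are deliberately not multiplicity-adjusted
across enhancers (the classification rule uses the raw p). Only full-width
bins are used so all observations have identical width; ANOVA on RPKM keeps
enhancer and shore groups comparable after clipping. Degenerate ANOVA
cases: all groups constant and equal → (F = 0, p = 1); perfect separation
with zero within-group variance → (F = ∞, p = 0).

## Strand-imbalance (R-loop) test

Windows of 500 bp are tiled at a 500 bp step (non-overlapping by default;
the step is a flag) across the supplied candidate peaks; a trailing window
survives iff it keeps ≥ half the window size. Counts are collected per
strand per replicate.

With ≥ 2 replicates per strand, each window gets a negative-binomial Wald
test (variance μ + αμ²):

1. size factors by DESeq2-style median-of-ratios (features with any zero
   excluded from the geometric means);
2. per-window dispersion by method-of-moments pooled across the two strand
   conditions (variances pooled by degrees of freedom);
3. an across-window mean–dispersion trend α(μ) = a₁/μ + a₀ fitted by least
   squares over **all** windows, negative moment estimates included so the
   fit stays unbiased;
4. per-window shrinkage: windows with a positive moment estimate take the
   equal-weight **arithmetic** average with the trend value; windows with a
   non-positive estimate (common at 2 replicates) take the trend alone;
   everything floored at 1e-8. The average is taken in linear rather than
   log space deliberately: the moment estimator is unbiased in linear
   space, and geometric averaging of a noisy unbiased estimate is
   downward-biased (Jensen), which deflates the Wald standard error and
   makes the test anticonservative at 2 replicates — the Monte-Carlo null
   calibration in the test-suite verifies the chosen form holds the nominal
   level;
5. log2FC on the strand means of normalized counts with a half-integer
   pseudo-count; delta-method SE under the NB variance; two-sided normal
   p-value; Benjamini–Hochberg adjustment across all tested windows.

With one replicate per strand the dispersion is unidentifiable and each
window gets a two-sided exact binomial test of the pooled plus count
against the library-size-adjusted global plus share.

Significant windows (padj ≤ 0.05) are merged per dominant strand with gap 0
(windows must touch) into R-loop regions. The R-loop density track is the
per-50 bp-bin |plus RPKM − minus RPKM|. A region is RNase-H *sensitive* iff
its mean density drops ≥ 1.5-fold from wild-type to treated (signal loss is
the reading of the fold threshold; the comparison direction is this
package's documented choice).

## Time-course classification

Three nested NB mean models per feature — constant (1 parameter), sigmoid
`h0 + (h1−h0)·σ(β(t−t1))` (4), and the impulse product of an entry and an
exit sigmoid `(1/h1)·[h0+(h1−h0)σ(β(t−t1))]·[h2+(h1−h2)σ(−β(t−t2))]` (6,
with t1 ≤ t2) — are fitted by bounded multi-start L-BFGS-B on log-scale
level and rate parameters (β ∈ [0.05, 20], levels ≥ 1e-6, t2 = t1 + dt with
dt > 0). The likelihood surface is multi-modal, so transition times are
initialized on the observed timepoint grid and around the empirical
extremum, and each model's start list includes the parameter configuration
that exactly reproduces the next-simpler model's optimum — which also
guarantees the nested log-likelihood ordering up to optimizer tolerance.
Dispersions are per-feature method-of-moments over replicate groups pooled
across timepoints, shrunk toward the across-feature trend exactly as in the
imbalance test, then held fixed during mean-model fits.

Classification: LRT impulse vs constant (df 5) → "any regulation"; LRT
impulse vs sigmoid (df 2) → "transience"; BH within each family; transient
requires both at padj ≤ 0.05, steady only the first. Direction compares the
fitted level at the internal extremum (transient) or at the last timepoint
(steady) with the fitted level at the first timepoint. The design is
case-only (no control series). The χ² reference for the LRTs is asymptotic
and the boundary constraints make it approximate; the null calibration
(≥ 90% of all-constant features called not-significant) is verified by
simulation.

## Synthetic data

The generators define the study conditions used throughout the tests:

* **KAS tags** — Poisson placement at per-kb rates promoter 10, gene body
  2, termination 4, background 0.1, scaled to 100 000 tags; 40
  non-overlapping genes (6–15 kb, both strands) on one chromosome; 100
  enhancers (1–1.5 kb) on a second chromosome (hence distal, ≥ 5 kb from
  every gene), half "paused" (element rate 4 vs shore rate 1 per kb), half
  "pass-through" (rate 4 across element and shores). Tags are placed by 5′
  position and extended through the real pipeline path.
* **spKAS windows** — 5000 balanced windows at NB(μ = 50, α = 0.05) per
  strand with 2 replicates (depth factors 1.0/1.2), plus 500 planted
  single-window regions at |log2FC| = 2 split symmetrically across strands;
  the RNase-H condition deflates the planted strand difference 4-fold at
  preserved total signal.
* **Time course** — 200 features per class (constant / monotone sigmoid /
  impulse pulse), baselines log-uniform in [30, 300], folds 4–8 in either
  direction, β ∈ [1, 3], transitions inside the sampled range, NB α = 0.05,
  6 timepoints (0, 1, 2, 4, 6, 8 h) × 2 replicates.

All randomness flows from one seed through named substreams, so outputs are
byte-reproducible and adding a generator does not shift existing streams.
These sizes keep the full suite and the acceptance script to a few minutes
on one CPU while leaving the Monte-Carlo tolerances meaningful.

What the generators do **not** emulate: sequence content and mappability,
GC structure (none modeled; no correction applied), chromatin-driven rate
heterogeneity, overlapping transcription units, biological replicate
variability beyond NB dispersion, and the guanine specificity of the
labeling chemistry. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under its stated model, not that the
thresholds are optimal for any particular real cell line.

## Known limitations

* The bin-level ANOVA ignores spatial autocorrelation (see above).
* The Wald test's normal reference is approximate at very low counts;
  windows with zero reads on both strands are reported untested (p = 1).
* Short (< 1 kb) genes and genes whose regions clip at chromosome ends are
  excluded from indices with reason codes rather than scored.
* The impulse optimizer can in principle miss a global optimum despite the
  multi-start scheme; fits are reported with all three log-likelihoods so
  downstream users can audit the orderings.
* RNase-H filtering compares density tracks, so it inherits the binning
  resolution (50 bp) of those tracks.
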