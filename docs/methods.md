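# Methods

This note documents the statistical models, the threshold rules, the
synthetic-data generator, and the design decisions behind `durens`.

## Normalization and filtering

Counts are scaled to counts per million (CPM) per sample; no between-sample
normalization beyond CPM (no TMM or quantile normalization) is applied, since
every downstream call is a rule on CPM or a count-based exact test that
equalizes depth internally.

Pseudocounts are **floors**, not addends: `max(cpm, floor)`. Two policies
exist — the per-condition 1st percentile of all CPM values in that
condition's samples (peak assays), and a flat floor of 1 CPM (genes). A floor
is monotone and idempotent, which keeps fold changes stable without inflating
high values. The percentile is computed over *all* features of the condition
group, not only expressed ones; this is configurable
(`pseudocount.percentile`).

The acute-abundance filter keeps a peak when its mean CPM over replicates in
at least one acute-stimulation condition (unstimulated, IFNγ 8 h, LPS 8 h by
default) ties or exceeds that condition's median of per-peak means.
Inclusive ties (`>=`) keep the filter monotone and reproducible; the
percentile (default 0.5) and the condition list are config. Percentile 0
keeps everything; percentile → 1 keeps only per-condition maxima.

## Differential testing

Induced peaks and washout contrasts use a conditional negative-binomial
exact test, the classic two-group construction:

1. **Depth equalization.** Every sample's counts are rescaled to the
   geometric-mean library size and rounded half-even (deterministic; no
   stochastic rounding).
2. **Dispersion.** Per-feature NB dispersion φ (variance = μ + φμ²) is
   estimated by method of moments on the depth-scaled counts within each
   group, pooled across the two groups by degrees of freedom. The common
   value is the *mean of the raw, signed* per-feature estimates over
   features with nonzero counts: raw moment estimates at 1–2 residual df are
   individually wild but mean-unbiased, whereas their median sits near half
   the truth (the median of a 1-df variance estimate is ≈ 0.46 of its mean),
   which would make the test anticonservative. Final per-feature dispersion
   is the convex blend `w·common + (1−w)·max(φ̂, 0)` with `w = 0.7`
   (`differential.shrinkage_weight`). With one replicate per group the
   estimate degenerates to common-only and callers should supply a prior.
3. **Exact p-value.** The sum of n i.i.d. NB(μ, φ) counts is NB(nμ, φ/n).
   Conditional on a feature's total across both groups, the reference-group
   sum has mass proportional to the product of the two group-sum NB masses;
   the two-sided p-value is the total probability of outcomes no more likely
   than the observed one (minimum-likelihood rule, ties included, with a
   1e-7 relative slack so floating-point noise cannot drop an exact tie).
   At φ = 0 this reduces exactly to a conditional binomial. The
   implementation enumerates the conditional support directly; the test
   suite verifies it against edgeR's `exactTest(rejection.region="smallp")`
   to ~1e-4 relative and against closed-form binomial enumeration at φ = 0.
4. **Fold changes and FDR.** log2 fold change is computed from pseudocounted
   group-mean CPM (treatment over reference) — matching how signal within
   peaks is quantified — not from the test's internal parameters.
   Benjamini–Hochberg (statsmodels) controls FDR across features. Induced:
   L2FC > 2 (strict) and FDR < 0.01 (strict).

This is a reimplementation in the spirit of edgeR's exact test, not a port:
on real data the feature-by-feature FDR list will not match edgeR's
(different dispersion machinery), and no claim of per-feature agreement is
made.

## Washout durability

**Persistence** of an induced feature is judged in the washout-versus-
*unstimulated* contrast: L2FC ≥ 0 (inclusive) and FDR < 0.01 (strict).
"Still above baseline" is only meaningful against the unstimulated control;
a washout-versus-8 h contrast would conflate decay with persistence.

**Population shifts** (e.g., "LPS-induced enhancers revert toward baseline")
are summarized by the mean per-feature log2 ratio of post- to pre-washout
condition means (pseudocounted) with a two-sided paired Wilcoxon signed-rank
test. Zero differences are dropped; for ≤ 25 remaining pairs the null
distribution of the positive rank sum is enumerated exactly by dynamic
programming over sign flips (midranks for tied magnitudes, so the exact path
handles ties); larger samples use the normal approximation with tie and
continuity corrections (scipy). The exact path is verified against full
2ⁿ sign-flip enumeration for n ≤ 12.

**Trajectory clustering**: per-feature profiles are log2 condition-mean CPM
across an ordered condition list, Z-scored per feature (mean 0, sd 1 across
the profile). Zero-variance features cannot be Z-scored and are excluded
explicitly (reported, not NaN-filled). k-means (scikit-learn, `n_init=10`,
fixed seed) with k = 3 by default — the washout patterns are
persist / decay / further-increase — and clusters are relabeled
deterministically by descending centroid value at the washout-media
coordinate, so label 0 is always the most-persistent pattern and repeated
runs are identical. Condition means (not individual replicates) are
clustered; replicate-level profiles are a caller choice by passing a
different matrix.

## Gene-level memory rules

All gene rules operate on condition-mean CPM floored at 1; replicates are
averaged before any ratio.

* **Induced**: CPM(stim 8 h) / CPM(unstim) ≥ 5, inclusive.
* **Persistence percent**: 100 × CPM(washout) / CPM(8 h), a plain ratio with
  no baseline subtraction, banded ≥90 / 20–90 / <20 (bands partition
  [0, ∞); 20 and 90 belong to the upper band at each boundary per the
  inclusive-≥ convention).
* **Potentiated**: (a) LPS-inducible — the naive (PBS-pretreated) arm
  reaches ≥ `lps_fold_min` (5 by default; 4 for the ruxolitinib-conditioned
  design) times the naive 0-h level somewhere on the course — and (b)
  pretreated/naive CPM ratio ≥ 2 at two *contiguous* timepoints.
  "Contiguous" means adjacent on the sampled grid ({0, 1, 3, 6, 12} h);
  clock-time adjacency is not computable on an irregular grid. The
  induction gate deliberately uses the naive arm: pretreatment-driven
  elevation alone must not qualify a gene as LPS-inducible.
* **Tolerized**: naive/pretreated ratio ≥ 2 at two contiguous timepoints,
  and ≥ 4-fold LPS induction in the ruxolitinib-conditioned arm (relative to
  that design's naive 0 h) — i.e., the gene must remain LPS-inducible when
  JAK signaling is blocked, otherwise reduced induction could reflect JAK
  dependence rather than tolerance.
* **Basal set-point**: log2(pretreated 0 h / naive 0 h) > 0.5, strict, with
  a 1e-9 slack so a ratio of exactly 2^0.5 lands in the equal-basal class.
  All other fold thresholds are inclusive (`≥`); the basal split is the one
  strict threshold, following its source convention.
* **Mean potentiation**: both arms' L2FC are referenced to the naive 0-h
  level, so the per-timepoint arm difference reduces to
  log2(pretreated(t)/naive(t)); the score averages this over timepoints
  *excluding* 0 h (both arms are defined relative to it; including it is a
  config option).

Potentiated and tolerized are computed from different criteria and are not
forced to be mutually exclusive.

## Enhancer–gene linkage

A peak links to every protein-coding gene whose TSS lies within ±20 kb of
the peak **midpoint** (inclusive), excluding promoter-proximal pairs
(±1 kb). Midpoint anchoring is symmetric and pinned; distance is signed by
gene strand (positive = downstream of the TSS). Gene-level uniqueness is not
imposed — a peak may link to several genes and vice versa, and each link
contributes one (mean potentiation, enhancer washout L2FC) pair. The
association is summarized by a Spearman rank correlation (robust to the
unknown, plausibly nonlinear scale coupling chromatin to expression); at
least 3 pairs are required.

## Synthetic-data generator

The generator draws NB counts (gamma–Poisson, variance μ + φμ²) from latent
log2-CPM means; all planted effects act on the latent mean, so counts stay
marginally NB. Library sizes are log-uniform within 2× of nominal, and the
recorded library size of each sample is its realized column sum. Same
config (including seed) produces byte-identical output files.

Defaults and what they emulate:

* ~10⁴ features per assay, 2 replicates per condition.
* Dispersion 0.2 for peak assays (tag counts in peaks are noisy at this
  level) and 0.05 for RNA-seq (expressed genes in a controlled in-vitro
  design are substantially less dispersed); nominal depths 2×10⁶ (reads in
  peaks) and 2×10⁷ (RNA-seq).
* Baseline abundance log2 CPM ~ U(2, 7). LPS-response genes draw baselines
  from U(1, 3): inflammatory cytokines/chemokines are near-silent before
  induction, which also keeps their induced mass a small share of the
  library (see the compositionality caveat below).
* Effects (log2): induction +4 at 8 h; the persistent class keeps the
  induced level minus 1 after washout in media (a persistent-but-dipped
  shape — with zero drop, the persistent and further-increasing classes
  become nearly inseparable in Z-score shape and no clustering could
  distinguish them); the increasing class gains a further +1; decaying
  returns to baseline; blockade arms (rux, anti-IFNγ) erase persistence for
  every class. Potentiation delta +1.5 at the late timepoints of the
  restimulation course (scaled per gene by a strength factor in [1, 1.4]),
  tolerance delta −1.5 at the middle timepoints, elevated-basal shift +2.
* Each potentiated gene is coupled to one persistent peak placed 3–15 kb
  from its TSS whose washout effect increases with the gene's planted mean
  potentiation; all uncoupled peaks are intergenic (>20 kb from every TSS).
  This plants the positive potentiation–durability rank correlation.
* A small fraction (2%) of null genes is flagged non-protein-coding to
  exercise the coding filter.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: peak-width and GC effects, fragment-level sampling,
batch structure, donor-to-donor variability, correlated features (peaks
under one domain), and — importantly — heavy **compositional coupling**. CPM
is compositional: if a large mass fraction of the library is induced, every
other feature's CPM shrinks and realized fold changes compress. The default
class fractions keep induced features a minority precisely so that planted
log2 effects survive in CPM space (a planted "8-fold" gene realizes ≈
7-fold at the default mass load). Recovery benchmarks quoted by the test
suite hold under those minority-fraction conditions; with, say, 10% of a
transcriptome induced 8-fold, no CPM-based rule can see the nominal fold —
that is arithmetic, not an implementation limit.

## Numerical choices

* Exact-test tie handling: outcomes with probability within 1e-7 relative of
  the observed one count as ties and are included in the p-value.
* Depth equalization rounds half-even; identical inputs give identical
  pseudo-counts on every platform.
* BH is order-preserving with the input and verified against the hand
  step-up on small cases.
* k-means uses a fixed `random_state` and 10 restarts; determinism of
  assignments is asserted in the suite.
* Degenerate inputs: zero library size, empty condition groups, k larger
  than the clusterable feature count, fewer than 2 nonzero Wilcoxon pairs,
  and fewer than 3 correlation pairs are all explicit errors, not silent
  results.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` regenerates each study design at sizes chosen to
estimate its quantity stably: 2000 peaks for null calibration and the
induced/persistence recoveries (with 150–200 planted features), 3000 peaks
for trajectory clustering, 10⁴ genes for the fivefold-induction recovery
(150 planted, so the compositional shave stays ≈ 0.1 log2), and 3000 genes /
3000 peaks for the potentiation, tolerance and coupling analyses (~75
potentiated, ~30 tolerized, ~60 couplings). All randomness derives from the
`--seed` argument.

## Known limitations

* The exact test reproduces the *method family* the peak analysis belongs
  to, not a specific tool's output; real-data induced lists will differ
  feature-by-feature from edgeR's (dispersion machinery differs), though the
  conditional exact p-value itself matches edgeR to numerical precision at
  fixed dispersion.
* Persistence classification inherits the power of the washout contrast: at
  2 replicates and peak-level dispersion 0.2, features with modest washout
  signal can fail FDR < 0.01 and be called non-persistent even when truly
  above baseline. This is a property of the calling rule, faithfully
  reproduced.
* The gene rules are pure threshold rules on mean CPM (no variance model),
  exactly as defined; they are sensitive to the pseudocount floor for genes
  near the detection limit.
* Merging of per-subject peak sets is out of scope: the pipeline accepts a
  pre-merged peak universe.
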