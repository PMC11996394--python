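# Methods

`trmsig` implements the computational analysis of a hashtag-multiplexed
droplet single-cell experiment on epidermal CD8⁺ tissue-resident memory
(T_RM) T cells: identifying cell-containing droplets, assigning cells to
their sample of origin, excluding low-quality cells, scoring cells and
groups against reference transcriptional-state gene signatures with a
randomized control, staging cells along a differentiation time course, and
the quantification statistics used to compare conditions. This note
documents the models, defaults and design choices.

## Synthetic data model

No external dataset ships with the package; every stage is exercised on
simulated experiments with known ground truth.

**Droplet experiment.** UMI counts of real cells are negative-binomial
around group-specific gene means: a shared relative-abundance profile is
drawn from a gamma distribution (shape 0.6 — strongly skewed, as UMI data
are), each transcriptional group's planted up-genes are multiplied by
`2^signature_effect`, and the profile is renormalized so the expected total
stays at `cell_mean_counts` (default 2,000 UMI). The dispersion parameter
`r` (default 2) is the NB size; per-gene variance is `m + m²/r`. Empty
droplets draw Poisson counts from the group-averaged ambient profile at
`empty_mean_counts` (default 50). Doublets are sums of two freshly sampled
cells from distinct samples, emitted in addition to `n_cells` at a rate of
`doublet_fraction` (default 5%).

**Protein (TotalSeq-C-like) panel.** Each cell's own hashtag is Poisson at
`hashtag_signal` (default 100), foreign hashtags at `hashtag_background`
(default 5, uniform across tags — the simplest ambient model that exercises
the demultiplexing rule). The panel additionally carries two isotype-control
channels (Poisson mean 1; a 2% "sticky" subpopulation at mean 30 on both)
and 12 generic surface markers at mean 60 counts. The surface markers exist
because a real panel spans ~100 antibodies: without them no simulated cell
could reach the 500-count antibody QC floor, and the antibody rank curve
would have no knee. Ambient protein in empty droplets is the in-cell
background scaled by `empty_mean_counts / cell_mean_counts` (same soup,
proportional capture); the composition of ambient material is not an
empirically constrained quantity, so it is a config knob rather than an
assertion.

**Dying cells.** A `mito_high_fraction` (default 5%) of cells have their
mitochondrial genes (named with the standard mouse `mt-` prefix) rescaled to
30% of the transcriptome against a 2% baseline, placing them firmly on the
removal side of the 10% QC boundary.

**Staged reference.** A bulk-like table emulating a T_RM differentiation
time course: a naive stage plus ordered timepoints (`d05, d10, …`), each
planting `genes_per_stage` up-regulated genes at the configured log2
fold-change. In the default *cumulative* mode a stage keeps all earlier
stages' genes up (differentiation as an accruing program); *exclusive* mode
plants each set at its own stage only and is what the recovery tests use,
since there the planted set per stage is exactly the DE truth. Samples are
drawn at 1,000,000 total counts — bulk-scale depth, at which a 4-fold
change on even low-abundance genes is detectable with ~20 samples per
stage.

**What the simulation does not model:** batch effects across lanes, ambient
RNA contamination inside real cells, gene–gene correlation structure,
variable capture efficiency per cell, or TCR/protein panels beyond the
hashtags and controls. Passing tests therefore demonstrate correctness of
the algorithms under idealized droplet noise, not robustness to every
artifact of real data.

## Cell calling

Barcodes are ranked by total count (descending, ties broken
lexicographically so curves are reproducible). The log10(total) versus
log10(rank) curve, restricted to positive totals, is smoothed with a
centered moving average (window 21 ranks — raw UMI curves are step-like and
a derivative on ties is undefined); the inflection is the rank minimizing
the first derivative within a search window of rank 10 to 99% of positive
barcodes, excluding the extreme head and tail where curvature estimates are
unstable. The returned threshold is the raw total just below the steepest
drop, and barcodes strictly above it are called. The "strictly above"
convention makes the two-plateau case unambiguous (100 barcodes at 1,000
over 1,000 at 10 calls exactly 100 cells). A curve whose search window
spans less than a 2-fold drop has no inflection and is rejected. Calling is
done independently on the RNA and antibody curves and intersected, since
cell-containing droplets are high in both.

## Demultiplexing

A cell is assigned to its top hashtag when that tag has at least
`min_counts` (10) counts and is *more than* `ratio` (2.0) times the second
most abundant tag — strict inequality for "more than double", inclusive for
"at least 10". Droplets with two positive tags (both at or above
`doublet_positive_threshold`, default 10) that fail the ratio test are
doublets, ties included; everything else is unassigned. The rule operates
on raw counts with no normalization, and the doublet-positivity threshold
is a separate parameter from the assignment floor because the two roles are
conceptually distinct even though both default to 10. This deterministic
rule replaces clustering-based hashtag demultiplexing; it is dependency-free
and exactly auditable on an integer grid.

## Quality control

Four conjunctive filters with literal boundary semantics: fewer than 500
RNA counts (499 removed, 500 kept); over 10% mitochondrial counts (exactly
10% kept); fewer than 500 antibody counts; positivity for two isotype
controls (one positive control is kept). Isotype "positivity" has no
quantified threshold in the protocol, so it defaults to the demultiplexing
positivity floor (10 counts) for consistent count-scale semantics, and is
configurable. Per-filter attrition is tallied against the full input —
a cell failing two filters counts under both — while the kept set is
defined by the conjunction. An empty mitochondrial gene set skips that
filter and records the skip rather than silently passing everything.

## Signature scoring

Expression is normalized to log scale — `log2(TPM+1)` for bulk tables with
gene lengths, `log2(CP10K+1)` for UMI matrices where length correction is
undefined — then each gene is centered across all cells. Centering is the
z-operation of the scoring pipeline: values are mean-subtracted but not
variance-scaled by default (an optional flag gives strict unit-variance
z-scores), which keeps the score linear in expression and removes any
per-gene additive offset. The score of a signature in a cell is the mean of
centered values over up-genes minus the mean over down-genes; a group's raw
score is the mean over its cells, with a normal-approximation 95% CI
(`mean ± 1.96·SE`; a bootstrap CI is not provided). Signature genes absent
from the matrix are dropped and counted.

**Randomized control.** Because the raw score depends on the number and
coverage of signature genes, the same statistic is computed on `n_iter`
(default 1,000) uniformly drawn gene sets of equal sizes, and the control
mean subtracted to give the adjusted score. Signature genes remain in the
sampling pool — excluding them shifts the control by less than sampling
error on exchangeable fixtures, and including them keeps the null exactly
size-matched. The group score is linear in expression, so the control is
evaluated on per-group mean profiles, which makes 1,000 iterations cheap at
any cell count. Control draws are deterministic given the seed, which is
mandatory in pipeline configs whenever a stochastic stage is enabled.

**Cell versus pseudobulk mode.** Whether a group's score averages per-cell
scores or scores the group's mean profile is ambiguous in general use, and
the two agree exactly for the raw score by linearity; both modes are
implemented and labeled in the output rather than collapsed. Pseudobulk
mode collapses centered cell profiles to per-condition means *without*
re-centering, so a one-cell condition reduces exactly to the cell-mode
result.

**Signature derivation.** Group-versus-reference signatures rank genes by a
two-sided Wilcoxon rank-sum test on log expression; up-genes are the
`top_n` (default 100) most significant with mean log fold-change ≥
`min_abs_lfc` (0.25) and p < 0.05, down-genes symmetrically. The p-gate
means identical groups yield near-empty signatures (false positives at
roughly the gate rate) instead of harvesting noise fold-changes. Shortfalls
are returned as shorter signatures with a recorded note.

## Trajectory staging

One signature per reference timepoint versus naive, in stage order; query
groups are scored against each with the randomized control, yielding a
profile over the time course plus the control band (the baseline is zero on
the adjusted scale; its sd gives the band width). Timepoint signatures use
up and down genes when both qualify, with an up-only flag, since "top
differentially expressed genes" does not fix a direction convention. This
is discrete per-timepoint scoring — no pseudotime or continuous trajectory
model is attempted.

## Quantification statistics

Cluster-frequency tables report counts and within-condition fractions
(absent clusters as zero), with an optional chi-square homogeneity test
labeled as an extension. Epidermal densities are mean per-image counts over
equal 1 mm² fields; unequal areas require explicit consent and then pool.
Paired and unpaired two-tailed t-tests follow the zero-variance convention
p = 1 when means are equal (so a vector tested against itself gives t = 0,
p = 1). Dunnett's two-sided many-to-one comparison uses the multivariate-t
distribution of the pooled-variance contrast statistics with seeded
randomized quadrature for the critical points; the reported unadjusted
p-value is the marginal p of the same statistic, which the adjusted value
dominates for any number of treatments, and a single treatment reduces to
the ordinary t-test decision.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use a 500-cell / 5,000-empty
default experiment, 200–300-gene scoring fixtures with 25–40 planted genes
and 30–50 cells per group, 50–100 seeded replicates for recovery and
divergence rates, 200–1,000 control iterations, and 5,000–10,000 null
replicates for t-test calibration — sizes at which every Monte-Carlo
assertion has comfortable margin while a full run stays in the tens of
seconds. Gene-centering is validated to 1e-8; oracle equivalence of the
scoring path is asserted to 1e-10. All randomness flows through
`numpy.random.default_rng` seeds carried in configs and results.

## Known limitations

- The knee detector assumes a two-regime curve; gradual ambient decay with
  no plateau separation (< 2-fold drop) is rejected rather than guessed at.
- The demultiplexing rule has no model of tag cross-talk beyond uniform
  background; heavily imbalanced tag loading would need the ratio re-tuned.
- Adjusted scores of mutually exclusive groups are anti-symmetric by
  construction when only two groups exist (centering forces the mirror
  image); interpretation should compare groups, not read single values as
  absolute enrichment.
- Dunnett p-values inherit the stochastic quadrature of the multivariate-t
  CDF; they are reproducible only at fixed seed and can move in the third
  decimal across seeds.
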