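# Methods

## Overview

`scdr` predicts drug response from gene expression by transferring
signatures learned on pharmacogenomically profiled cell lines to any new
expression profile, bulk or single-cell. The method has three stages:

1. **Resistant/sensitive labelling.** For a drug *d*, every trained cell
   line has an AUC — the area under its percent-viability dose-response
   curve, so higher AUC means more surviving cells, i.e. more resistance.
   Lines with AUC strictly above `mean + k·sd` are labelled resistant (R),
   strictly below `mean − k·sd` sensitive (S); the band between is left
   unlabelled. Mean and sd are taken over all lines measured for that drug,
   with the sample (n−1) standard deviation. Default `k = 0.8`.

2. **Signature derivation.** Per gene, the signature weight is the log2
   fold change of group means, `log2((mean_R + c) / (mean_S + c))`, with a
   pseudocount `c` (default 0.01) keeping ratios finite when a gene is
   silent in one group. The drug's signature (its drug-response genes,
   DRGs) is the `n_top` most up-regulated plus the `n_top` most
   down-regulated genes (default 200 + 200), each carrying its log2FC as a
   signed weight.

3. **Scoring.** The dataset to be scored is standardized gene-wise across
   *its own* samples, `z_im = (x_im − mean_i)/sd_i` (sample sd). The
   drug-response score of sample *m* is the weight-averaged z-score over
   the `q` signature genes present in the matrix:

   `DRS_dm = (1/q) · Σ_i log2FC_id · z_im`

   Higher scores predict resistance. For single-cell data, cell scores are
   averaged per cell line (mDRS) when line-level truth is the unit of
   validation.

Because each z row averages zero, scores for any drug average zero over the
scored samples; because standardization removes gene-wise location and
scale, scores are invariant under per-gene positive affine transforms of
the expression values; and because the labelling rule uses only
standardized distances, R/S labels are invariant under positive affine
transforms of the AUC scale. All three facts are enforced as tests.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 0.8 | AUC threshold multiplier for R/S labelling (sd units) |
| `n_top` | 200 | genes per signature side (up and down) |
| `pseudocount` | 0.01 | added to group means before the log-ratio (expression units) |
| `min_group_size` | 2 | minimum lines per side for a drug to be trainable |
| `alpha` | 0.05 | significance level defining an "accurate" separation |
| `folds` | 3 | cross-validation folds |
| `permutations` | 100 | CV re-shufflings per drug |
| `scale` | 10⁴ | library-size normalization target (counts per cell) |
| QC thresholds | 200 / 0.20 / 3 | min genes per cell, max mitochondrial fraction, min cells per gene |

Fold change is a ratio of linear-scale means. A matrix flagged log-scale is
rejected at signature derivation unless the caller passes
`allow_log_scale=True`, acknowledging that group means will then be taken
on the log scale — the two choices give different rankings and the
difference should never be silent.

## Statistical validation

**Separation tests.** Per drug, a one-sided Wilcoxon rank-sum test of
whether resistant samples score higher than sensitive ones; `p < alpha`
counts the drug as accurately predicted, and accuracy over a panel is the
fraction of accurate drugs. The null distribution is enumerated exactly
whenever both groups have ≤ 8 members and the scores are tie-free;
otherwise the normal approximation with tie and continuity corrections is
used. The exact branch is verified against full permutation enumeration in
the tests.

**Cross-validation.** R and S lines are shuffled and split separately into
`folds` near-equal groups; fold *f* pairs the *f*-th groups as the held-out
test set, the signature is re-derived on training lines only, held-out
scores are min–max rescaled to [0,1] within each test (a constant vector
maps to 0.5), and each fold of each permutation contributes one separation
test — `folds × permutations` tests per drug. Tests whose training split
loses a whole class are excluded from the denominator and counted.

**Concordance (WPCI).** The weighted probabilistic concordance index
compares predicted scores against the AUC over all unordered line pairs
with unequal AUC. Each pair is weighted by
`Φ(|ΔAUC| / (noise_sd·√2))` — the probability that the observed AUC
ordering is the true one if each measurement carries independent Gaussian
noise with standard deviation `noise_sd` — and earns concordance credit 1,
0.5 (prediction tie) or 0. `noise_sd` defaults to 0.1 × the sample sd of
the shared AUC values. Absolute WPCI values depend on `noise_sd`; which of
two methods ranks higher does not (property-tested), and with unit weights
the statistic reduces exactly to the classical concordance index. Method
comparison reports per-drug WPCI for both methods, the fraction of drugs
where one exceeds the other, and a one-sided Wilcoxon signed-rank p-value
on the paired per-drug values.

**Calibration is assessed out-of-sample.** Evaluating separation on the
same samples the signature was derived from is circular: the top genes are
selected for exactly the R-vs-S contrast being tested, so even with zero
true signal the in-sample "accuracy" is essentially 100% (we measure 1.0
on null data). The null-calibration analyses therefore derive signatures on
one cohort and evaluate on an independent cohort whose labels come from its
own independent AUC draws; measured null accuracy then sits inside the
binomial 95% band around alpha. In-sample accuracy is still a meaningful
descriptive statistic for real signal — it is how the discovery-cohort
analysis is framed — but it cannot calibrate.

## Synthetic cohorts

The generator emulates the two layers the pipeline consumes, at desk scale.

* **Bulk expression.** Per-gene baselines are log-normal
  (`log2 ~ N(3, 1.5)`); per-line values add `N(0, noise_sd²)` log2 noise
  (default 0.5). A planted set of `n_signature_up + n_signature_down` genes
  (default 200 + 200 of 2000) is shifted by ±`effect_log2fc/2` in resistant
  lines and ∓`effect_log2fc/2` in sensitive lines, so the designed R-vs-S
  log2 fold change is exactly `effect_log2fc` while intermediate lines stay
  at baseline. The symmetric placement matters: it keeps sensitive and
  intermediate lines distinguishable in signature-gene space, so AUC-based
  labelling can recover the designed split while the intermediates populate
  the unlabelled middle band the thresholding rule is supposed to produce.
* **AUC.** Each line's true activity is the mean z-scored planted-gene
  signal (down-genes sign-flipped); AUC mixes standardized activity with
  independent Gaussian noise in proportion `auc_coupling : 1 − auc_coupling`
  (default 0.9) and is affine-mapped to a plausible positive range — the
  labelling rule is affine-invariant, so the particular scale is
  irrelevant. Cohort defaults are 30 resistant, 30 sensitive and 30
  intermediate lines.
* **Single-cell counts.** Per line, cells draw a log-normal library size
  around 5000 counts, gene means follow the line's expression profile
  rescaled to that size, counts are negative binomial with shape
  `nb_dispersion` (default 2; variance μ + μ²/θ) and are thinned by
  Bernoulli dropout (default rate 0.3) — the minimal standard model of
  10x-style overdispersion and sparsity.

What the generator does **not** emulate: batch and cell-cycle structure,
gene–gene correlation beyond the planted signature, doublets, ambient RNA,
multiple drugs sharing target pathways, and the heavy-tailed AUC
distributions of real dose-response panels. Passing tests therefore show
that the statistics behave as designed under their own model assumptions,
not that real-cohort accuracies are reproduced.

## Numerical and design choices

* Genes with zero mean in both groups are dropped before ranking rather
  than scored 0, so they cannot dilute top-N selection; ranking ties break
  lexicographically on gene id so builds are deterministic.
* Zero-variance genes are removed before scoring (their z-score is
  undefined), so `q` counts scoreable genes only; the removal is logged.
* Sparse matrices are standardized in dense row batches of 2048 genes; the
  result is value-identical to the dense computation (tested).
* Duplicate gene rows in dense input collapse by mean with a warning;
  duplicate sample columns are an error. Gene identifiers match by exact
  string equality after whitespace trimming — no symbol/accession aliasing.
* QC runs cells-then-genes in one pass each (cell filters are stated before
  the gene filter, and gene detection depends on retained cells);
  mitochondrial genes are recognized by configurable id prefix (default
  `MT-`). Re-applying QC to its own output is a no-op on realistic data,
  though not a theorem: removing genes can in principle push a borderline
  cell below the detected-genes threshold on a second pass.
* Small-sample separation tests are discrete: with 4-vs-4 groups the
  one-sided exact p-values have support k/70, so the attainable type-I
  level at alpha 0.05 is 2/70 ≈ 0.029. Under permuted labels,
  cross-validation is additionally conservative because training and
  held-out portions of a fixed class are sampled without replacement and
  their compositions anti-correlate, reversing chance-selected genes in the
  held-out fold. Permuted-label CV accuracy therefore sits at or below —
  not at — alpha; the validity-relevant direction (no inflation) is what
  the test suite asserts.

## Problem sizes

The test and acceptance analyses run at reduced scale: bulk cohorts of
2000 genes × 90 lines, 500 simulated null drugs, threefold CV with 5
(planted) or 100 (null) permutations on 12 + 12 lines, and 100 single-cell
replicates of 20 lines × 100 cells × 500 genes. These sizes exercise every
code path with comfortable statistical margins while keeping a full run in
well under a minute for the suite and about twenty seconds for the
acceptance script.

## Known limitations

* Scores are relative to the scored dataset (z-scores are computed on it),
  so scores are comparable within a dataset, not across datasets; the CV
  procedure's [0,1] rescaling exists for exactly this reason.
* A signature trained on cell lines carries cell-line biology; applying it
  to tissue requires the usual caveats about stroma and immune admixture.
* WPCI's absolute value depends on the assumed measurement-noise scale;
  report comparisons, not absolute values, across settings.
* The pseudocount bounds attainable |log2FC| for silent genes at
  `log2(mean/c)`; with the default c = 0.01 this is far beyond any real
  ranking boundary, but a pseudocount of 0 re-enables infinite fold changes
  for genes expressed in exactly one group.
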