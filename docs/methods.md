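# Methods

`crcmeta` implements a complete fecal-metagenome case-control analysis:
relative-abundance profiles in, a cross-validated sparse classifier,
consensus marker signature, and evaluation statistics out. This note
documents the models, the numerical conventions, the synthetic cohort the
package is validated on, and the design choices that were genuinely open.

## Abundance model and normalization

Profiles are features x samples matrices of **relative abundances**: each
feature's share of a sample's total sequencing signal, with the unmapped
remainder included in the denominator, so column sums are at most 1.

Processing is a fixed three-step chain, fitted once on the training
population and frozen:

1. **Low-abundance filter.** A feature is kept only if its abundance
   *exceeds* a threshold in at least one sample (strict `>`). Defaults:
   1e-3 for taxonomic features, 1e-4 for functional or combined spaces.
2. **Log transform.** `log10(x + x0)` with pseudocount `x0` = 1e-6
   (taxonomic) or 1e-8 (functional), chosen below the detection floor of
   the respective feature space.
3. **Smoothed standardization.** Each feature is centered to mean 0 and
   divided by `sigma_f + q10`, where `sigma_f` is its standard deviation
   (ddof = 1, the R convention) and `q10` is the 10th percentile
   (linear-interpolation) of all per-feature standard deviations. The
   additive smoothing keeps near-constant features from being inflated.
   `q10` is computed on retained features, after filtering.

The fitted `NormalizationState` (mask, pseudocount, centers, smoothed
scales) is a frozen, pure function: external cohorts are transformed with
the training parameters, never re-estimated. By default the state is
fitted on the full cross-validation population *before* partitioning —
this mirrors the protocol's stated step order and makes external
validation exactly reproducible, at the cost of a small information leak
from test folds into the centering statistics (not into model fitting or
penalty tuning). A `normalization="within-fold"` option refits the chain
inside each training fold; it is the scope under which the leakage-guard
test (perturbing a test sample leaves its fold's model bit-identical)
holds exactly.

## Classification protocol

Labels: cases are all CRC stages (AJCC 0–IV); controls are neoplasia-free
participants plus small-adenoma (< 10 mm) patients; large adenomas and IBD
samples are excluded from the labeled set but can be scored at prediction
time.

The classifier is an ensemble of L1-penalized (LASSO) logistic regressions
fitted with LIBLINEAR, in ten-times-resampled stratified 10-fold
cross-validation:

- **Penalty tuning.** Inside each training fold, a nested stratified
  5-fold CV scores each candidate penalty by the area under the
  precision-recall curve (average precision with step interpolation) of
  the *pooled* inner-test predictions. Pooling (rather than per-fold
  averaging) was chosen for stability at small n. Candidates are then
  tried in descending score order and the first whose refit on the full
  training subset keeps **at least 5 nonzero coefficients** wins; if none
  qualifies, the least-penalized candidate is used and flagged.
- **Penalty grid.** 20 geometric values from `lambda_max` (the smallest
  penalty that zeroes every coefficient at the null model — the glmnet
  convention) down to `lambda_max / 1000`. `lambda` is the reciprocal of
  LIBLINEAR's `C`: the objective is `||w||_1 + (1/lambda) * sum_i c_i *
  logloss_i`.
- **Class weighting.** Controls receive 5x the per-example weight of
  cases (`c_i`), tilting models toward high specificity, the regime a
  screening test operates in.
- **Aggregation.** Each sample's score is the mean of its 10 test-fold
  predictions (one per repetition); external cohorts are scored by all
  100 models and averaged.

Determinism: one integer seed drives the CV plan, the inner folds and the
LIBLINEAR solver; identical configuration and seed reproduce the ensemble
bit-for-bit.

## Consensus marker signature

For each model, a feature's weight share is `100 |w_f| / sum_g |w_g|`.
The signature consists of features with a nonzero coefficient in **at
least 50%** of the ensemble's models (inclusive threshold), ordered by
mean weight share; the reported coefficient is the mean signed log-odds
across all models (zeros included). Models with all-zero weight vectors
contribute zero support and are excluded from the share averaging (and
counted).

## Univariate statistics and community descriptors

- **Rank tests.** Two groups: Wilcoxon rank-sum; for combined n <= 20 the
  permutation null of the rank sum is enumerated exactly by dynamic
  programming over doubled midranks (ties handled exactly), otherwise the
  tie-corrected normal approximation is used. More than two groups:
  Kruskal–Wallis.
- **FDR.** Benjamini–Hochberg step-up (the standard default where the
  correction method is otherwise unspecified).
- **Fold change** is the difference of group-wise medians of
  log10-transformed abundances. The functional significance ruleset
  (adjusted p < 0.01 and linear fold change > 1.33) applies the cutoff as
  `|Delta log10 median| > log10(1.33) ~ 0.1239`; the taxonomic ruleset is
  adjusted p < 0.1 with no fold-change criterion. Setting alpha = 1 or
  the fold-change cutoff to 1 disables that criterion.
- **Diversity.** Shannon index in natural-log units over each sample's
  renormalized nonzero abundances (the vegan convention); richness is the
  nonzero-feature count. The Bacteroidetes:Firmicutes ratio sums lineage
  metadata per phylum; a zero denominator yields a missing value.

## Evaluation statistics

- **AUC** is the Mann–Whitney probability with ties counted 0.5; ROC
  curves enumerate all distinct thresholds. Classification at a boundary
  predicts "case" strictly above the threshold.
- **TPR at a target FPR** uses the most permissive threshold whose
  empirical FPR does not exceed the target (conservative step
  interpolation; no optimistic linear interpolation at small n).
- **DeLong test** for paired AUC differences uses the standard structural
  component covariance estimator (0.5 tie kernel). Degenerate zero
  variance (identical scores) reports z = 0, p = 1.
- **Bootstrap TPR test**: paired stratified bootstrap (cases and controls
  resampled separately, both classifiers evaluated on the same
  replicate); the one-sided p-value is the fraction of replicates where
  the TPR difference at the target FPR is <= 0. Default 2000 replicates.
- **TPR confidence band**: stratified percentile bootstrap over an FPR
  grid, anchored to (united with) the empirical curve so the band always
  contains the point estimate; anchoring can only increase coverage. The
  band method behind the original shaded intervals is not documented
  anywhere we could follow, so this explicit construction is our choice.
- **Operating point**: `choose_threshold` returns the smallest threshold
  whose specificity meets a target, rather than hard-coding any fixed
  boundary.

## Ordination and progression

PCA is centered (not variance-scaled) on log10 abundances, with a
deterministic sign convention (largest-magnitude loading positive).
Progression uses four ordered groups — 1 no neoplasia, 2 adenoma (any
size), 3 CRC AJCC 0–II, 4 CRC III–IV — with Spearman correlation of PC1
against the ordinal group and pairwise Wilcoxon tests (unadjusted by
default, mirroring per-pair plot annotations; a BH switch exists).
PCoA is classical metric scaling (double-centered Gram eigendecomposition);
negative eigenvalues are dropped with their magnitude logged. The default
sample distance is Bray–Curtis on raw abundances — the distance behind the
original ordination is not stated, so this common microbiome choice is
documented rather than implied.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces heavy-tailed, zero-inflated compositional profiles
with known ground truth:

- Per-feature log10-normal base abundances: locations uniform on
  (-6, -2), scales on (0.4, 1.0) — a community spanning six orders of
  magnitude with a few dominant taxa.
- Bernoulli presence per feature (default prevalence 0.9) for zero
  inflation; per-sample renormalization to `1 - unmapped fraction`
  (uniform on (0.1, 0.4)), so profiles are compositions with an explicit
  unmapped remainder.
- **Planted markers** shift the case-group location by a signed log10
  effect before renormalization. Marker features draw their base location
  from a moderate-abundance band, (-3.8, -3.0) ~ 1e-4..1e-3, and are
  present with probability 1 by default. Both choices are coherence
  requirements of the planted-truth contract, not conveniences: markers
  below the low-abundance filter would have their truth removed by the
  protocol's first step, a marker drawn at the top of the abundance range
  would dominate the community when enriched and leak class signal into
  every other feature through closure, and class-independent zeros in
  markers would make the Bayes-optimal score zero-gated and hence outside
  the linear family the classifier fits. They also match the abundance
  band real CRC marker species occupy.
- Covariates: cases' ages are shifted (+8 years by default), emulating
  the age confounding of real screening cohorts; an imperfect binary
  screen (sensitivity 0.30, specificity 0.95 — the regime of a guaiac
  fecal occult blood test) is simulated per sample; cohort-level batch
  effects add per-feature location offsets with configurable scale.
- Every cohort carries its true per-sample generative log-odds (zero
  contribution from absent markers; closure ignored), whose empirical AUC
  is the oracle ceiling the pipeline is compared against.

Renormalization makes non-marker features weakly class-dependent
(compositional leakage); with the default marker band this effect is
second-order and accepted as realistic.

A note on batch shifts and linear scorers: a cohort-wide per-feature
location offset moves every sample's linear score by the same constant,
which leaves rank-based metrics (AUC) untouched to first order; the
external-validation AUC therefore degrades only through second-order
channels (sigmoid saturation, zero inflation, closure), slowly but
monotonically in the shift scale, while score calibration degrades
immediately.

Not emulated: phylogenetic correlation between features, read-level
sequencing error (no FASTQ simulation), longitudinal sampling, and
abundance-prevalence coupling. Passing the recovery tests therefore shows
the protocol recovers location-shift signals in compositional,
zero-inflated data of realistic dimensionality — it does not certify
performance on real cohorts, where effect structure is richer and batch
effects are not Gaussian.

## Problem sizes used in the shipped checks

The recovery condition is 300 features, 10 markers with |Delta log10| = 1,
75 cases / 75 controls, full protocol defaults (10x resampled 10-fold CV,
nested 5-fold tuning, 20-point grid): the test suite averages 10 generator
seeds; the acceptance script reports 5 seeds for the recovery block and 3
for null calibration, which keeps its full run in the minutes range while
leaving the per-seed conditions untouched.

## Known limitations

- Global normalization (the default, matching the protocol's step order)
  leaks test-fold information into centering statistics; use
  `within-fold` scope when strict leakage-freedom matters more than
  protocol fidelity.
- The null distribution of the aggregated CV score is slightly
  anti-conservative in AUC terms (overfit fold models generalize slightly
  below chance), a known property of resampled CV with tuned learners;
  the null-calibration test bounds this drift.
- The exact rank-sum branch is O(n * 2^n)-ish via subset-sum counting and
  is capped at combined n = 20.
- `two_step_counts` resolves multi-mapped reads by unique-count
  proportionality in a single pass; no iterative (EM-style) refinement.
- Consensus support is computed across all r x k models, which share
  training samples across repetitions; support values are therefore
  correlated between models and should not be read as independent
  replication.
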