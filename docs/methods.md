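# Methods

This note documents the models, defaults and numerical choices behind
`neuropathsel`, in the order the pipeline runs.

## Synthetic cohort model

The generator emulates the structure of a post-mortem brain-donation
cohort whose real data is access-controlled. Each subject carries a
latent standard-Gaussian **dementia liability** `L`. Dementia status is
assigned by ranking liabilities: after drawing the label-unknown subset
completely at random (9 of 186 by default), the highest-liability
subjects among the rest become the dementia cases, so the configured
class counts (107 / 70 by default) are hit exactly for every seed.

Each feature has a latent score `z = effect_size · L + u` with
unit-variance noise `u`. Features sharing a block identifier (CAA, TSA,
microinfarct) draw `u = √λ·B + √(1−λ)·ε` from a per-block factor `B`,
where `λ` is `block_loading` (default 0.8); this single parameter
reproduces the three clusters of within-block rank correlations seen in
such data (Spearman ρ ≳ 0.7 at λ = 0.9). Ordinal and binary features
are cut from `z` at equal-probability thresholds (keeping every level
populated); numeric features are an affine map of `z` onto their stated
range (±3 SD spans the range), rounded to integers. Missingness is
injected completely at random per feature at the schema's per-feature
rate. Generation is a pure function of the seed.

**Effect-size defaults.** The tau-staging analogs (Braak, BrainNet tau:
1.1; Thal phase: 0.95) are set clearly above all other features
(≤ 0.6) so that the features the field regards as primary dementia
correlates dominate every ranking method; the CAA/TSA/microinfarct
blocks carry moderate shared effects (0.2–0.5); sex and tufted
astrocytes are null; brain weight loads negatively (−0.5). The
hippocampal-tau analog combines a solid effect (0.6) with 48%
missingness, so it ranks highly yet is excluded by the missingness
rule — the behavior the pipeline is designed to handle.

**What the generator does not emulate.** The label is a deterministic
threshold on the same liability that drives every feature, so the
synthetic cohort is *more separable* than real neuropathology data
(best mean F1 typically 80–90% and consensus misclassification 10–20%,
versus ~74% and ~40% reported for comparable real cohorts, where
dementia occurs without proportionate pathology and vice versa).
Passing tests therefore validate the machinery — formulas, filtering
arithmetic, determinism, recovery of planted structure — not the
clinical difficulty of the task. Missingness is MCAR; real missingness
is likely informative. Ordinal cutpoints are equal-probability; real
stage distributions are skewed.

## Cohort preparation

- Ordinal stages are stored as integer codes in level order; binary
  presence/absence as 0/1; the label column is 1/0/empty.
- Brain weight is z-scored within sex (population SD of observed
  values); a zero-variance sex stratum is an error naming the stratum.
- The train fraction rounds half-up (`n·f + 0.5` floored), the only
  rule consistent with an 80/34 split of 114 at 70%.
- The Spearman screen uses pairwise-complete observations with midrank
  ties; pairs with fewer than 3 complete observations are undefined
  (NaN). Redundancy clusters are connected components of the
  |ρ| > 0.7 graph.
- Class balancing downsamples the majority class uniformly without
  replacement and shuffles rows, all driven by one seed. The
  complete-case subjects excluded by balancing are retained as the
  frozen holdout table.
- Features are dropped for missingness by their *empirical* rate
  against a configurable threshold (default 0.45), not by name.

## Feature ranking

- Numeric features are discretized by equal-frequency binning (default
  5 bins) for the contingency/entropy statistics; ReliefF uses raw
  values with range-normalized differences. Equal-frequency binning is
  robust to the skewed counts typical of staging data.
- Missing values enter the contingency/entropy statistics as an
  explicit extra category, and are imputed per class (mode; median for
  numeric) for ReliefF distances, so no subject is dropped at this
  stage.
- ReliefF is the canonical form — subtract the mean difference to the
  k nearest hits, add the class-prior-weighted mean difference to the
  k nearest misses, average over probes. A ratio of hit to miss
  differences is degenerate whenever hit differences vanish, so it is
  not used. Defaults: k = 10, an exhaustive deterministic pass over all
  instances (no sampling noise at n ≤ 200).
- Variable analysis is the Euclidean magnitude of the
  (min-max-normalized chi-square, min-max-normalized IG) vector.
- A zero expected contingency cell can only arise from an empty margin;
  empty margins are dropped with a warning before the chi-square sum.
- Constant features get gain ratio and symmetrical uncertainty 0, with
  a warning.
- Ranking ties break by original column order (stable sorts
  throughout), for reproducibility.

**Contribution scales.** Two normalizations coexist deliberately:

1. *Contributions* (reported, plotted, used for ordering): per method,
   min-max normalize then rescale to unit sum; contribution = 100 ×
   mean share. These sum to 100 across features.
2. *Selection threshold*: applied to each method's min-max-normalized
   score × 100 (a 0–100 scale per method). A "≥ 5 under every method"
   rule on the unit-sum scale would be unsatisfiable for more than 20
   features (shares average 100/36 ≈ 2.8); on the per-method min-max
   scale it admits a realistic shortlist of ~20–25 features.

## Classification benchmark

- Classifier hyperparameters: logistic regression (L2, C = 1, 2000
  iterations), 5-NN (uniform weights, Minkowski), LDA (SVD solver),
  SVMs (C = 1, RBF gamma "scale" or linear kernel), decision tree and
  Gaussian NB at library defaults. The resolved parameter maps are
  written to the run log (`classifier_config.json`).
- No feature scaling before classifiers by default: features are
  bounded ordinal codes on comparable scales (configurable through
  hyperparameters where needed).
- Zero-denominator metrics are NaN, never silently 0; means over
  repeats are NaN-aware.
- Per-repeat splits come from counter-derived seeds
  (`SeedSequence(seed)`), so results are bit-identical given the master
  seed and repeats are independent. A degenerate single-class training
  fold is discarded, logged, and replaced. Only the split is
  re-randomized across repeats; the balancing draw is fixed upstream.

## Consensus misclassification

- The LOOCV outcome grid covers every classifier × nested-subset
  combination; stochastic learners are seeded per column.
- The clustered profile is the binary correctness vector (correct = 1)
  **plus one coordinate for the true label**. Correctness alone cannot
  separate a consistently-false-positive subject from a
  consistently-false-negative one (identical vectors); the label
  coordinate — which is exactly what distinguishes FP from FN — makes
  the three-cluster cut well defined while changing distances between
  same-label subjects not at all.
- Average linkage, Euclidean distance, dendrogram cut at k = 3 by
  default (configurable).
- Cluster labels by majority cell content; a cluster with at least half
  its cells correct is "correct"; ties between FP and FN fall back to
  "correct".
- The misclassification rate counts subjects whose majority outcome
  over the grid is FP or FN; exact fractions are reported (no
  rounding-induced mismatch between the total and the FP + FN split).
- Cluster contrasts use Welch's two-sided t-test per feature between
  the FP and FN clusters; a feature constant in both groups is
  undefined (NaN).

## Signature explanation

- SVM-RFE: linear SVC (C = 1), one feature eliminated per iteration by
  smallest |hyperplane weight|, ties to the first (stable input
  order). Features are standardized before each fit by default because
  |w| ranking is scale-sensitive.
- Stability: M = 100 subject subsamples by default (80%, stratified by
  target, without replacement; degenerate draws redrawn and logged).
  Survival frequencies per signature size sum to the size.
- Consensus signatures (top-s by frequency) are scored by XGBoost at
  library defaults (seeded, single-threaded) under leave-one-out
  cross-validation; per-subsample signatures are available as an
  alternative mode.
- The signature size is chosen by the one-standard-error rule on the
  F1 curve; the SE per size comes from a seeded nonparametric
  bootstrap (200 draws) over the held-out predictions.
- The combined re-evaluation unions the top classical features
  (default 8) with the non-standard pool (7 regional features plus
  age, brain weight, sex; duplicates collapsed with a warning),
  re-runs the LOOCV consensus analysis, reports age-stratified rates
  (≥ 85 vs < 85 years) and the holdout sensitivity contrast. The
  balanced table is complete-case only with respect to the selected
  classical features, so residual missing cells in the union columns
  are median-imputed (computed over observed values) before this run.

## Problem sizes

The test suite and the acceptance script run the pipeline at a reduced
size chosen to keep a laptop-class run comfortable: 50 repeated splits
(instead of 500) and 20 RFE subsamples (instead of 100), with the full
classifier set, both sweep directions and the full LOOCV grid. Monte
Carlo checks use 20 seeds (recovery, monotonicity, null associations),
100 repeated splits for the chance-level null, and 50 subsamples for
RFE recovery.

## Known limitations

- The single-liability generative model cannot produce genuinely
  discordant cases (dementia with no pathology signal); the FP/FN
  clusters on synthetic data are boundary cases, not distinct
  aetiologies.
- MCAR missingness understates the difficulty of real missingness.
- The stepwise benchmark inherits the instability of small test sets
  (34 subjects); SDs over repeats are reported for exactly this
  reason.
- No imputation model: missing-category and median imputation are
  deliberately simple, matching the removal-based design they support.
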