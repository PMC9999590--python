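# neuropathsel

Feature ranking and misclassification analysis for neuropathology-based
dementia classification.

## The problem

Post-mortem brain-donation cohorts score each donor on dozens of
semi-quantitative neuropathology features — Braak neurofibrillary tangle
stage, Thal amyloid phase, BrainNet tau stage, CERAD-style plaque scores,
cerebral amyloid angiopathy (CAA) severity by region, thorn-shaped
astrocyte (TSA) presence, microinfarct counts — together with the
donor's dementia status at death. Two questions follow naturally:

1. **Which features carry the most information about dementia?**
   Different filter statistics rank features differently, so a single
   ranker is not trustworthy on its own.
2. **Where does neuropathology fail to explain dementia?** Some donors
   are misclassified by *every* model — demented cases with little
   recorded pathology (false negatives) and non-demented cases with
   substantial pathology (false positives).

`neuropathsel` implements a complete pipeline for both questions, for
cohort tables of ordinal/nominal/numeric features with missingness and a
binary (possibly missing) dementia label.

## The method

**Ensemble filter ranking.** Seven model-independent statistics score
each feature *X* against the label *Y*:

- chi-square: X² = Σ (O−E)²/E over the class × level contingency table;
- information gain: IG = H(Y) − Σ_v p(v) H(Y | X=v) (bits);
- gain ratio: IG / H(X);
- symmetrical uncertainty: SU = 2·IG / (H(X) + H(Y)) ∈ [0, 1];
- ReliefF: W[X] accumulates, over probe subjects, the mean difference to
  the k nearest same-class neighbours (subtracted) and the
  prior-weighted mean difference to the k nearest other-class
  neighbours (added);
- least loss: L² = Σ_{i,j} [P(Y_i, X_j) − P(Y_i)P(X_j)]²;
- variable analysis: |V| = √(chi² + ig²) on the min-max-normalized
  chi-square and information-gain scores.

Per method, weights are min-max normalized and rescaled to unit sum;
the **percentage contribution** of a feature is 100 × its mean share
across methods (contributions sum to 100). Features scoring at least a
threshold (default 5 on the per-method 0–100 scale) under *every*
method form the shortlist; demographics and features above a
missingness threshold (default 45%) are then excluded.

**Stepwise benchmark.** Seven classifiers (logistic regression, decision
tree, 5-NN, LDA, Gaussian naive Bayes, RBF- and linear-kernel SVM) are
trained on nested subsets of sizes 1..K grown from the top- (forward) or
bottom-ranked (backward) feature, over repeated random 70/30 splits of
the class-balanced cohort, reporting accuracy, balanced accuracy, F1,
precision, sensitivity and specificity (mean ± SD over repeats).

**Consensus misclassification.** Every classifier × subset combination
is re-run under leave-one-out cross-validation; each subject's outcome
(TP/FP/TN/FN) over the whole grid forms a profile. Profiles are
clustered (average linkage, Euclidean) and cut into three clusters:
correct, false positive, false negative. The misclassification rate is
the share of subjects whose majority outcome is FP or FN.

**Signature explanation.** For each cluster, a one-vs-rest target is
ranked by linear-SVM recursive feature elimination on many stratified
subject subsamples of the *non-standard* pool (regional pathology
features plus age, brain weight, sex). Survival frequencies give a
consensus signature per size; each is scored by an XGBoost classifier
under leave-one-out cross-validation, and the final size is the
smallest within one standard error of the best F1. Finally the top
classical features and the non-standard pool are combined and the
consensus misclassification analysis is re-run — the contrast that
shows whether non-standard pathology carries residual signal.

**Synthetic cohort.** The cohort the pipeline was designed around is
access-controlled, so the package ships a generator that emulates its
printed structure: 186 subjects (107 dementia / 70 without / 9 with
unknown status), the 44-feature schema with per-feature missingness
rates, monotone dementia gradients across staging levels, and three
blocks of correlated features (CAA, TSA, microinfarcts) driven by
shared latent factors. See `docs/methods.md` for the generative model.

## Worked example

```python
import neuropathsel as nps

cohort = nps.generate_cohort(seed=1)          # 186 subjects, 44 features
labeled = nps.filter_missing_labels(cohort)   # drops the 9 status-unknown
print(labeled.n_subjects)                     # 177

pool = [f for f in labeled.feature_names
        if f not in nps.NONSTANDARD_FEATURES] + ["age", "brain_weight"]
scores = nps.rank_features(labeled, features=pool, seed=1)   # 7 methods x 36 features
profile = nps.aggregate_contributions(scores)
print(profile.contributions.sort_values(ascending=False).head(4))
# brainnet_tau_stage           10.69
# thal_phase                    8.95
# hippocampal_tau_nft_stage     8.89
# braak_nft_stage               5.27
```

The strongly tau-associated staging features dominate the aggregate
contribution, mirroring their role as primary dementia correlates; the
numbers are percentages of the total contribution (all 36 sum to 100).

The full pipeline is one call (or `neuropathsel run` on the command
line):

```python
summary = nps.run_pipeline("out/", seed=1, repeats=50, rfe_subsamples=20)
print(summary["best_f1_pct"])               # 90.2  (best mean F1, %)
print(summary["misclassification_pct"])     # 12.2  (majority-wrong subjects, %)
print(summary["combined_misclassification_pct"])  # 9.5 (classical+non-standard)
```

`out/` then holds every artifact: the cohort CSV and schema, the
Spearman redundancy screen, per-method weight tables, contribution
profile, selected features, the benchmark sweep (TSV + curves), the
LOOCV outcome matrix and heatmap, cluster assignments, per-cluster
signatures and the combined re-evaluation.

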