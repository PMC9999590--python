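"""Explaining the misclassification clusters from non-standard
pathology and demographic features.

For each outcome cluster (correct / false positive / false negative) a
one-vs-rest target is built and a linear-SVM recursive feature
elimination (RFE) is run on many random subject subsamples: at every
iteration the feature with the smallest absolute hyperplane weight is
pruned.  Survival frequencies across subsamples give a consensus
signature per size; each consensus signature is scored with a
gradient-boosted tree classifier under leave-one-out cross-validation,
and the final signature size is picked by the one-standard-error rule
on the F1 curve.

The module also re-runs the misclassification analysis on the union of
the top classical features and the non-standard pool, the contrast the
clusters motivate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .classification_bench import (
    ClassifierSpec,
    MetricSet,
    compute_metrics,
    confusion_from_predictions,
    holdout_eval,
)
from .cohort_prep import CohortTable
from .misclassification_consensus import (
    OutcomeMatrix,
    loocv_outcomes,
    misclassification_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "svm_rfe_rank",
    "subsample_stability",
    "SignatureCurve",
    "Signature",
    "signature_curve",
    "choose_signature",
    "combined_feature_eval",
]


def _impute_observed(table: CohortTable, features: list[str]) -> pd.DataFrame:
    """Median-impute (mode for binaries is the rounded median here)
    residual missing cells so distance/weight-based learners can run."""
    sub = table.data[features].astype(float)
    return sub.fillna(sub.median())


def svm_rfe_rank(
    table: CohortTable,
    target: pd.Series,
    features: list[str] | None = None,
    C: float = 1.0,
    standardize: bool = True,
) -> list[str]:
    """Linear-SVM recursive feature elimination.

    Iteratively fits a linear soft-margin SVM on the surviving features,
    ranks them by absolute hyperplane weight and prunes the weakest, one
    per iteration, until one survives.  Returns the elimination order
    reversed, i.e. most persistent feature first.  Deterministic given
    the data and ``C``.  Features are standardized before each fit by
    default, since |w| ranking is scale-sensitive.
    """
    features = list(features) if features is not None else table.feature_names
    y = np.asarray(target.loc[table.subject_ids], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("target has a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    X_all = _impute_observed(table, features)

    surviving = list(features)
    eliminated: list[str] = []
    while len(surviving) > 1:
        X = X_all[surviving].to_numpy()
        if standardize:
            X = StandardScaler().fit_transform(X)
        est = SVC(kernel="linear", C=C)
        est.fit(X, y)
        w = np.abs(est.coef_).ravel()
        worst = int(np.argmin(w))  # ties: first (stable input order)
        eliminated.append(surviving.pop(worst))
    eliminated.append(surviving[0])
    return eliminated[::-1]


def subsample_stability(
    table: CohortTable,
    target: pd.Series,
    features: list[str] | None = None,
    M: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Survival frequency of every feature at every signature size over
    ``M`` random subject subsamples (stratified by target, without
    replacement).

    Returns a size x feature frame; row ``s`` holds the fraction of
    subsamples in which each feature survived into the final ``s``
    features, so each row sums to ``s``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    features = list(features) if features is not None else table.feature_names
    y = target.loc[table.subject_ids]
    rng = np.random.default_rng(seed)
    idx_by_class = {v: np.flatnonzero(y.to_numpy() == v) for v in np.unique(y)}

    counts = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, len(features) + 1, name="size"), columns=features
    )
    done = 0
    attempts = 0
    while done < M:
        attempts += 1
        if attempts > 20 * M:
            raise RuntimeError("could not draw valid stratified subsamples")
        rows: list[int] = []
        for v, members in idx_by_class.items():
            take = max(2, int(round(subsample_fraction * len(members))))
            if take > len(members):
                logger.warning("class too small for stratified subsample; redrawing")
                take = len(members)
            rows.extend(rng.choice(members, size=take, replace=False).tolist())
        sub_ids = table.subject_ids[sorted(rows)]
        sub = table.with_data(table.data.loc[sub_ids])
        if y.loc[sub_ids].nunique() < 2 or min((y.loc[sub_ids] == v).sum() for v in idx_by_class) < 2:
            logger.warning("degenerate subsample redrawn")
            continue
        order = svm_rfe_rank(sub, target, features, C=C)
        for s in range(1, len(features) + 1):
            counts.loc[s, order[:s]] += 1.0
        done += 1
    return counts / M


@dataclass
class SignatureCurve:
    """Leave-one-out performance of the consensus signature per size."""

    sizes: list[int]
    accuracy: list[float]
    f1: list[float]
    f1_se: list[float]
    signatures: dict[int, list[str]]          # size -> consensus feature list
    selection_frequency: pd.DataFrame         # size x feature survival frequency


@dataclass
class Signature:
    cluster: str
    features: list[str]
    score: MetricSet

    @property
    def size(self) -> int:
        return len(self.features)


def consensus_signatures(frequency: pd.DataFrame) -> dict[int, list[str]]:
    """Top-s features by survival frequency per size (ties broken by
    column order, stable)."""
    out = {}
    for s in frequency.index:
        freqs = frequency.loc[s].to_numpy()
        order = np.argsort(-freqs, kind="stable")[: int(s)]
        out[int(s)] = [frequency.columns[i] for i in order]
    return out


def _loocv_counts(X: np.ndarray, y: np.ndarray, seed: int):
    est = XGBClassifier(n_jobs=1, random_state=seed, verbosity=0, eval_metric="logloss")
    pred = cross_val_predict(est, X, y, cv=LeaveOneOut(), n_jobs=1)
    return pred


def signature_curve(
    table: CohortTable,
    target: pd.Series,
    frequency: pd.DataFrame,
    seed: int = 0,
    sizes: list[int] | None = None,
    bootstrap: int = 200,
) -> SignatureCurve:
    """Score the consensus signature of every size with a boosted-tree
    one-vs-rest classifier under leave-one-out cross-validation.

    The standard error of F1 per size is estimated by a seeded
    nonparametric bootstrap over the held-out predictions.
    """
    sigs = consensus_signatures(frequency)
    sizes = sizes if sizes is not None else sorted(sigs)
    y = np.asarray(target.loc[table.subject_ids], dtype=int)
    rng = np.random.default_rng(seed)

    acc, f1, f1_se = [], [], []
    for s in sizes:
        X = _impute_observed(table, sigs[s]).to_numpy()
        pred = _loocv_counts(X, y, seed)
        ms = compute_metrics(confusion_from_predictions(y, pred))
        acc.append(ms.accuracy)
        f1.append(ms.f1)
        boots = []
        n = len(y)
        for _ in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            bms = compute_metrics(confusion_from_predictions(y[idx], pred[idx]))
            if np.isfinite(bms.f1):
                boots.append(bms.f1)
        f1_se.append(float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0)
    return SignatureCurve(
        sizes=list(sizes), accuracy=acc, f1=f1, f1_se=f1_se,
        signatures=sigs, selection_frequency=frequency,
    )


def choose_signature(curve: SignatureCurve, cluster: str = "") -> Signature:
    """One-standard-error rule: the smallest size whose F1 is within one
    SE (at the best size) of the best F1."""
    if not curve.sizes:
        raise ValueError("empty signature curve")
    f1 = np.asarray(curve.f1, dtype=float)
    best = int(np.nanargmax(f1))
    threshold = f1[best] - curve.f1_se[best]
    chosen = best
    for i in range(len(curve.sizes)):
        if np.isfinite(f1[i]) and f1[i] >= threshold:
            chosen = i
            break
    size = curve.sizes[chosen]
    feats = curve.signatures[size]
    return Signature(
        cluster=cluster,
        features=feats,
        score=MetricSet(
            accuracy=curve.accuracy[chosen], balanced_accuracy=float("nan"),
            f1=curve.f1[chosen], precision=float("nan"),
            sensitivity=float("nan"), specificity=float("nan"),
        ),
    )


def combined_feature_eval(
    table: CohortTable,
    classical_top: list[str],
    nonstandard: list[str],
    specs: list[ClassifierSpec],
    seed: int = 0,
    holdout: CohortTable | None = None,
    holdout_spec: ClassifierSpec | None = None,
    age_feature: str = "age",
    age_cut: float = 85.0,
) -> dict:
    """Re-run the consensus misclassification analysis on the union of
    the top classical features and the non-standard pool.

    Returns the classical-only and combined misclassification
    percentages (overall and stratified at ``age_cut`` years), plus the
    holdout metric contrast when a holdout table is supplied.  Residual
    missing cells in the union columns are median-imputed.
    """
    union = list(dict.fromkeys(list(classical_top) + list(nonstandard)))
    if len(union) != len(classical_top) + len(nonstandard):
        logger.warning("duplicate features collapsed in the combined set")

    imputed = table.copy()
    imputed.data[union] = _impute_observed(table, union)
    subsets_classical = [list(classical_top)]
    subsets_combined = [union]

    m_classical = loocv_outcomes(imputed, subsets_classical, specs, seed=seed)
    m_combined = loocv_outcomes(imputed, subsets_combined, specs, seed=seed)
    result = {
        "classical_misclassification_pct": misclassification_rate(m_classical),
        "combined_misclassification_pct": misclassification_rate(m_combined),
    }

    age = table.data[age_feature] if age_feature in table.data.columns else None
    if age is not None and age.notna().any():
        for tag, mask in (("ge85", age >= age_cut), ("lt85", age < age_cut)):
            if mask.sum() == 0:
                continue
            for label, m in (("classical", m_classical), ("combined", m_combined)):
                sub = OutcomeMatrix(outcomes=m.outcomes.loc[mask], labels=m.labels.loc[mask])
                result[f"{label}_misclassification_pct_{tag}"] = misclassification_rate(sub)

    if holdout is not None:
        spec = holdout_spec or specs[0]
        ho = holdout.copy()
        ho.data[union] = _impute_observed(holdout, union)
        result["holdout_classical"] = holdout_eval(imputed, ho, list(classical_top), spec, seed=seed)
        result["holdout_combined"] = holdout_eval(imputed, ho, union, spec, seed=seed)
    return result
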