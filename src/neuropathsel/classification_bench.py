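"""Stepwise subset classification benchmark.

Seven classical classifiers are trained on nested feature subsets
(sizes 1..K, grown from the top- or bottom-ranked feature) over
repeated random 70/30 splits, and six confusion-matrix metrics are
reported as mean +/- SD across repeats:

    accuracy    = (TP + TN) / n
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = TP / (TP + (FP + FN) / 2)
    balanced accuracy = (sensitivity + specificity) / 2

A metric whose denominator is zero is reported as NaN (undefined),
never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort_prep import CohortTable, split_train_test

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "default_classifier_specs",
    "ConfusionCounts",
    "MetricSet",
    "METRIC_NAMES",
    "compute_metrics",
    "confusion_from_predictions",
    "build_subsets",
    "SweepResult",
    "evaluate_subsets",
    "holdout_eval",
]

CLASSIFIER_NAMES = (
    "logistic_regression",
    "decision_tree",
    "knn",
    "lda",
    "gaussian_nb",
    "svm_rbf",
    "svm_linear",
)

METRIC_NAMES = ("accuracy", "balanced_accuracy", "f1", "precision", "sensitivity", "specificity")


@dataclass
class ClassifierSpec:
    """Named classifier with its hyperparameter map."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def build(self, random_state: int | None = None):
        """Instantiate the scikit-learn estimator.

        Stochastic learners (decision tree tie-breaking) receive
        ``random_state`` for determinism; the others ignore it.
        """
        hp = dict(self.hyperparameters)
        if self.name == "logistic_regression":
            return LogisticRegression(**{"penalty": "l2", "C": 1.0, "max_iter": 2000, **hp})
        if self.name == "decision_tree":
            return DecisionTreeClassifier(random_state=random_state, **hp)
        if self.name == "knn":
            return KNeighborsClassifier(
                **{"n_neighbors": 5, "weights": "uniform", "metric": "minkowski", **hp}
            )
        if self.name == "lda":
            return LinearDiscriminantAnalysis(**{"solver": "svd", **hp})
        if self.name == "gaussian_nb":
            return GaussianNB(**hp)
        if self.name == "svm_rbf":
            return SVC(**{"kernel": "rbf", "C": 1.0, "gamma": "scale", **hp})
        if self.name == "svm_linear":
            return SVC(**{"kernel": "linear", "C": 1.0, "gamma": "scale", **hp})
        raise ValueError(f"unknown classifier {self.name!r}")

    def resolved_hyperparameters(self) -> dict:
        """The estimator's full parameter map after defaults resolve
        (for the run log)."""
        return self.build(random_state=0).get_params()


def default_classifier_specs(names: tuple[str, ...] = CLASSIFIER_NAMES) -> list[ClassifierSpec]:
    return [ClassifierSpec(name) for name in names]


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    accuracy: float
    balanced_accuracy: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The six confusion-matrix metrics; zero-denominator ratios are NaN."""
    if c.n <= 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    return MetricSet(
        accuracy=_ratio(c.TP + c.TN, c.n),
        balanced_accuracy=(sens + spec) / 2.0,
        f1=_ratio(c.TP, c.TP + (c.FP + c.FN) / 2.0),
        precision=_ratio(c.TP, c.TP + c.FP),
        sensitivity=sens,
        specificity=spec,
    )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# Subsets and the sweep


def build_subsets(ranked: list[str], direction: str = "forward") -> list[list[str]]:
    """Nested subsets of sizes 1..K.

    ``forward`` grows from the top-ranked feature downward; ``backward``
    from the bottom-ranked upward.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    source = list(ranked) if direction == "forward" else list(ranked)[::-1]
    return [source[: i + 1] for i in range(len(source))]


@dataclass
class SweepResult:
    """Mean/SD of every metric per (classifier, direction, subset size)."""

    table: pd.DataFrame  # long format: classifier, direction, subset_size, metric, mean, sd
    repeats: int

    def mean(self, classifier: str, subset_size: int, metric: str, direction: str = "forward") -> float:
        t = self.table
        row = t[
            (t.classifier == classifier)
            & (t.direction == direction)
            & (t.subset_size == subset_size)
            & (t.metric == metric)
        ]
        return float(row["mean"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _matrix(table: CohortTable, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table.data[features].astype(float).to_numpy()
    y = table.label.astype(int).to_numpy()
    return X, y


def evaluate_subsets(
    table: CohortTable,
    subsets: list[list[str]],
    specs: list[ClassifierSpec],
    train_fraction: float = 0.7,
    repeats: int = 500,
    seed: int = 0,
    direction: str = "forward",
) -> SweepResult:
    """Repeated-split benchmark of every classifier on every subset.

    Each repeat draws a fresh train/test split from a counter-derived
    seed; a degenerate single-class training fold is discarded (logged)
    and a replacement drawn.  Results are bit-identical for identical
    seeds.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    ss = np.random.SeedSequence(seed)
    split_seeds = ss.generate_state(4 * repeats) % (2**31)

    # Precompute the splits once; reuse across classifiers and subsets.
    splits = []
    counter = 0
    while len(splits) < repeats:
        if counter >= len(split_seeds):
            raise RuntimeError("could not draw enough non-degenerate splits")
        train, test = split_train_test(table, train_fraction, int(split_seeds[counter]))
        counter += 1
        if train.label.nunique() < 2:
            logger.warning("degenerate single-class training fold discarded")
            continue
        splits.append((train, test))

    records = []
    for spec in specs:
        for subset in subsets:
            per_repeat = {m: [] for m in METRIC_NAMES}
            for r, (train, test) in enumerate(splits):
                Xtr, ytr = _matrix(train, subset)
                Xte, yte = _matrix(test, subset)
                est = spec.build(random_state=int(split_seeds[r]))
                est.fit(Xtr, ytr)
                metrics = compute_metrics(confusion_from_predictions(yte, est.predict(Xte)))
                for m in METRIC_NAMES:
                    per_repeat[m].append(getattr(metrics, m))
            for m in METRIC_NAMES:
                vals = np.array(per_repeat[m], dtype=float)
                with np.errstate(invalid="ignore"):
                    records.append(
                        {
                            "classifier": spec.name,
                            "direction": direction,
                            "subset_size": len(subset),
                            "metric": m,
                            "mean": float(np.nanmean(vals)),
                            "sd": float(np.nanstd(vals, ddof=1)) if repeats > 1 else 0.0,
                        }
                    )
    return SweepResult(table=pd.DataFrame.from_records(records), repeats=repeats)


def holdout_eval(
    train: CohortTable, holdout: CohortTable, features: list[str], spec: ClassifierSpec,
    seed: int = 0,
) -> MetricSet:
    """Fit once on ``train``, evaluate on the disjoint ``holdout`` set."""
    overlap = train.subject_ids.intersection(holdout.subject_ids)
    if len(overlap):
        raise ValueError(f"holdout overlaps training set: {list(overlap)[:5]}")
    missing = [f for f in features if f not in holdout.data.columns]
    if missing:
        raise KeyError(f"features absent from holdout: {missing}")
    Xtr, ytr = _matrix(train, features)
    Xho, yho = _matrix(holdout, features)
    est = spec.build(random_state=seed)
    est.fit(Xtr, ytr)
    return compute_metrics(confusion_from_predictions(yho, est.predict(Xho)))
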