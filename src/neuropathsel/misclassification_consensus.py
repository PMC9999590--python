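"""Consensus misclassification analysis.

Every (classifier, feature-subset) combination is run under
leave-one-out cross-validation, each held-out subject's outcome is
recorded as TP/FP/TN/FN, and subjects are clustered on their outcome
profiles (average-linkage, Euclidean) to expose the cases that are
misclassified irrespective of classifier and feature set: the
false-positive cluster (pathology without recorded dementia) and the
false-negative cluster (dementia with insufficient recorded pathology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .classification_bench import ClassifierSpec, _matrix
from .cohort_prep import CohortTable

__all__ = [
    "OutcomeMatrix",
    "ClusterAssignment",
    "loocv_outcomes",
    "misclassification_rate",
    "cluster_outcomes",
    "cluster_feature_ttests",
]

OUTCOMES = ("TP", "FP", "TN", "FN")
CLUSTER_LABELS = ("correct", "false_positive", "false_negative")


@dataclass
class OutcomeMatrix:
    """Subjects x (classifier, subset_size) grid of TP/FP/TN/FN strings."""

    outcomes: pd.DataFrame   # cells are outcome strings
    labels: pd.Series        # true label per subject (1/0)

    @property
    def correctness(self) -> pd.DataFrame:
        """Binary view: 1 = correct (TP/TN), 0 = misclassified (FP/FN)."""
        return self.outcomes.isin(["TP", "TN"]).astype(float)

    def majority_outcome(self) -> pd.Series:
        """Per subject: FP/FN if misclassified in more than half of the
        runs (misses split by the true label), else correct."""
        wrong = 1.0 - self.correctness.mean(axis=1)
        out = pd.Series("correct", index=self.outcomes.index)
        mis = wrong > 0.5
        out[mis & (self.labels == 1)] = "FN"
        out[mis & (self.labels == 0)] = "FP"
        return out


def _outcome(y_true: int, y_pred: int) -> str:
    if y_true == 1:
        return "TP" if y_pred == 1 else "FN"
    return "FP" if y_pred == 1 else "TN"


def loocv_outcomes(
    table: CohortTable,
    subsets: list[list[str]],
    specs: list[ClassifierSpec],
    seed: int = 0,
) -> OutcomeMatrix:
    """Leave-one-out outcome matrix over the classifier x subset grid.

    Each cell records how the held-out subject was classified by a model
    trained on all other subjects.  Stochastic learners are seeded per
    column for determinism.
    """
    y = table.label.astype(int)
    columns: dict[tuple[str, int], list[str]] = {}
    ss = np.random.SeedSequence(seed)
    col_seeds = iter(ss.generate_state(len(specs) * len(subsets)) % (2**31))
    for spec in specs:
        for subset in subsets:
            X, yv = _matrix(table, subset)
            est = spec.build(random_state=int(next(col_seeds)))
            pred = cross_val_predict(est, X, yv, cv=LeaveOneOut(), n_jobs=1)
            columns[(spec.name, len(subset))] = [
                _outcome(t, p) for t, p in zip(yv, pred)
            ]
    frame = pd.DataFrame(columns, index=table.subject_ids)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["classifier", "subset_size"])
    return OutcomeMatrix(outcomes=frame, labels=y)


def misclassification_rate(m: OutcomeMatrix) -> float:
    """Percentage of subjects whose majority outcome is FP or FN."""
    if m.outcomes.empty:
        raise ValueError("empty outcome matrix")
    majority = m.majority_outcome()
    return float(100.0 * (majority != "correct").mean())


def outcome_fractions(m: OutcomeMatrix) -> dict[str, float]:
    """Percentages of subjects whose majority outcome is FP resp. FN."""
    majority = m.majority_outcome()
    return {
        "false_positive_pct": float(100.0 * (majority == "FP").mean()),
        "false_negative_pct": float(100.0 * (majority == "FN").mean()),
    }


@dataclass
class ClusterAssignment:
    """Subject -> {correct, false_positive, false_negative} plus the
    dendrogram linkage that produced it."""

    assignment: pd.Series
    linkage_matrix: np.ndarray
    cut_k: int

    def members(self, label: str) -> pd.Index:
        return self.assignment.index[self.assignment == label]


def cluster_outcomes(m: OutcomeMatrix, k: int = 3) -> ClusterAssignment:
    """Average-linkage Euclidean clustering of subjects on their binary
    correctness profiles, cut into ``k`` clusters.

    The clustered profile is the binary correctness vector plus one
    coordinate for the true label: two subjects wrong in exactly the
    same runs but on opposite sides of the diagnosis (a pure-FP vs a
    pure-FN profile) are otherwise indistinguishable, and the label
    coordinate is what lets the cut separate the false-positive from
    the false-negative cluster.

    Each cluster is labeled by the majority content of its cells:
    mostly-correct clusters are ``correct``; among the misclassified
    cells of the remaining clusters, majority FP vs FN decides the
    label (ties toward ``correct``).
    """
    n = len(m.outcomes)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} subjects")
    profiles = np.column_stack(
        [m.correctness.to_numpy(), m.labels.to_numpy(dtype=float)]
    )
    if k == 1:
        cluster_ids = np.ones(n, dtype=int)
        Z = linkage(profiles, method="average", metric="euclidean") if n > 1 else np.empty((0, 4))
    else:
        Z = linkage(profiles, method="average", metric="euclidean")
        cluster_ids = fcluster(Z, t=k, criterion="maxclust")

    assignment = pd.Series("", index=m.outcomes.index, dtype=object)
    for cid in np.unique(cluster_ids):
        rows = cluster_ids == cid
        cells = m.outcomes.iloc[rows].to_numpy().ravel()
        frac_correct = np.isin(cells, ["TP", "TN"]).mean()
        if frac_correct >= 0.5:
            label = "correct"
        else:
            fp = (cells == "FP").sum()
            fn = (cells == "FN").sum()
            if fp > fn:
                label = "false_positive"
            elif fn > fp:
                label = "false_negative"
            else:
                label = "correct"
        assignment.iloc[rows] = label
    return ClusterAssignment(assignment=assignment, linkage_matrix=Z, cut_k=k)


def cluster_feature_ttests(
    table: CohortTable,
    assignment: ClusterAssignment,
    features: list[str],
    groups: tuple[str, str] = ("false_positive", "false_negative"),
) -> pd.DataFrame:
    """Welch two-sample, two-sided t-test per feature between two
    clusters (default: false positives vs false negatives).

    A feature with zero variance in both groups is reported as NaN
    (undefined).
    """
    a_ids = assignment.members(groups[0])
    b_ids = assignment.members(groups[1])
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("both compared clusters must be non-empty")
    rows = []
    for name in features:
        a = table.data.loc[a_ids, name].dropna().astype(float)
        b = table.data.loc[b_ids, name].dropna().astype(float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t_stat, p = float("nan"), float("nan")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"feature": name, "t": t_stat, "p": p})
    return pd.DataFrame(rows).set_index("feature")
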