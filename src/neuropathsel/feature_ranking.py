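"""Filter-based feature ranking and ensemble contribution aggregation.

Seven model-independent scoring statistics relate each feature to the
dementia label:

* **chi2** -- Pearson chi-square: sum over contingency cells of
  ``(O - E)^2 / E``.
* **info_gain** -- Shannon information gain in bits:
  ``H(label) - sum_v p(v) H(label | feature = v)``.
* **gain_ratio** -- information gain divided by the feature's own
  entropy ``H(feature)``.
* **sym_uncertainty** -- ``2 IG / (H(feature) + H(label))``, in [0, 1].
* **relieff** -- canonical ReliefF: for each probe instance, subtract
  the mean per-feature difference to its k nearest same-class
  neighbours (hits) and add the class-prior-weighted mean difference to
  its k nearest other-class neighbours (misses).
* **least_loss** -- ``sum_{i,j} [P(Y_i, X_j) - P(Y_i) P(X_j)]^2``, the
  squared deviation of the joint distribution from independence.
* **variable_analysis** -- the Euclidean magnitude of the vector of the
  feature's min-max-normalized chi-square and information-gain scores.

Per-method weights are turned into percentage contributions by min-max
normalizing each method's weight vector, rescaling to unit sum, and
averaging the resulting shares across methods (x100, so contributions
sum to 100).

Numeric features are discretized by equal-frequency binning before the
contingency/entropy statistics; missing values enter those statistics
as an explicit extra category, and are replaced by the per-class mode
(numeric: median) for ReliefF distances, so no subject is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_prep import CohortTable

__all__ = [
    "METHODS",
    "ContingencyTable",
    "RankerScores",
    "ContributionProfile",
    "chi_square_score",
    "information_gain_score",
    "gain_ratio_score",
    "symmetrical_uncertainty_score",
    "relieff_score",
    "relieff_weights",
    "least_loss_score",
    "variable_analysis_score",
    "rank_features",
    "aggregate_contributions",
    "select_features",
]

METHODS = (
    "chi2",
    "info_gain",
    "gain_ratio",
    "sym_uncertainty",
    "relieff",
    "least_loss",
    "variable_analysis",
)

MISSING_CATEGORY = "__missing__"


# ---------------------------------------------------------------------------
# Contingency machinery


@dataclass
class ContingencyTable:
    """Class x level contingency table with expected counts and
    probability views."""

    observed: np.ndarray  # classes x levels
    n: int

    @classmethod
    def from_columns(cls, feature: pd.Series, label: pd.Series) -> "ContingencyTable":
        f = feature.astype(object).where(feature.notna(), MISSING_CATEGORY)
        ok = label.notna()
        tab = pd.crosstab(label[ok], f[ok])
        return cls(observed=tab.to_numpy(dtype=float), n=int(tab.to_numpy().sum()))

    @property
    def expected(self) -> np.ndarray:
        row = self.observed.sum(axis=1, keepdims=True)
        col = self.observed.sum(axis=0, keepdims=True)
        return row @ col / self.n

    @property
    def joint_prob(self) -> np.ndarray:
        return self.observed / self.n

    @property
    def class_marginals(self) -> np.ndarray:
        return self.observed.sum(axis=1) / self.n

    @property
    def level_marginals(self) -> np.ndarray:
        return self.observed.sum(axis=0) / self.n


def chi_square_score(c: ContingencyTable) -> float:
    """Pearson chi-square statistic. Levels or classes with zero margin
    (zero expected counts) are dropped with a warning."""
    obs = c.observed
    keep_rows = obs.sum(axis=1) > 0
    keep_cols = obs.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("empty contingency margins dropped before chi-square")
        obs = obs[np.ix_(keep_rows, keep_cols)]
    n = obs.sum()
    if n == 0 or obs.shape[0] < 1 or obs.shape[1] < 1:
        return 0.0
    exp = obs.sum(axis=1, keepdims=True) @ obs.sum(axis=0, keepdims=True) / n
    return float(((obs - exp) ** 2 / exp).sum())


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain_score(feature: pd.Series, label: pd.Series) -> float:
    """IG = H(label) - H(label | feature), in bits."""
    c = ContingencyTable.from_columns(feature, label)
    obs = c.observed
    h_label = _entropy(obs.sum(axis=1))
    level_n = obs.sum(axis=0)
    h_cond = sum(
        (level_n[j] / c.n) * _entropy(obs[:, j]) for j in range(obs.shape[1]) if level_n[j] > 0
    )
    return h_label - h_cond


def gain_ratio_score(feature: pd.Series, label: pd.Series) -> float:
    """IG normalized by the feature's entropy; 0 (with a warning) for a
    constant feature."""
    c = ContingencyTable.from_columns(feature, label)
    h_feature = _entropy(c.observed.sum(axis=0))
    if h_feature == 0.0:
        warnings.warn("constant feature: gain ratio defined as 0")
        return 0.0
    return information_gain_score(feature, label) / h_feature


def symmetrical_uncertainty_score(feature: pd.Series, label: pd.Series) -> float:
    """SU = 2 IG / (H(feature) + H(label)), in [0, 1]."""
    c = ContingencyTable.from_columns(feature, label)
    h_feature = _entropy(c.observed.sum(axis=0))
    h_label = _entropy(c.observed.sum(axis=1))
    denom = h_feature + h_label
    if denom == 0.0:
        warnings.warn("degenerate columns: symmetrical uncertainty defined as 0")
        return 0.0
    return 2.0 * information_gain_score(feature, label) / denom


def least_loss_score(c: ContingencyTable) -> float:
    """Sum of squared deviations of the joint distribution from the
    product of its marginals."""
    joint = c.joint_prob
    prod = np.outer(c.class_marginals, c.level_marginals)
    return float(((joint - prod) ** 2).sum())


def variable_analysis_score(chi_norm: float, ig_norm: float) -> float:
    """Magnitude of the (normalized chi-square, normalized IG) vector."""
    return float(np.hypot(chi_norm, ig_norm))


# ---------------------------------------------------------------------------
# ReliefF


def _relieff_prepare(
    table: CohortTable, features: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Impute missing cells per class (mode for discrete, median for
    numeric) and compute per-feature value ranges for the diff metric."""
    labels = table.label.astype(float).to_numpy()
    X = table.data[features].astype(float).to_numpy().copy()
    is_numeric = np.array(
        [table.meta_for(f).kind == "numeric" if _has_meta(table, f) else True for f in features]
    )
    for j, name in enumerate(features):
        col = X[:, j]
        for cls in np.unique(labels):
            sel = labels == cls
            vals = col[sel]
            nan = np.isnan(vals)
            if nan.any():
                observed = vals[~nan]
                if observed.size == 0:
                    fill = 0.0
                elif is_numeric[j]:
                    fill = float(np.median(observed))
                else:
                    uniq, cnt = np.unique(observed, return_counts=True)
                    fill = float(uniq[np.argmax(cnt)])
                vals[nan] = fill
                col[sel] = vals
    ranges = X.max(axis=0) - X.min(axis=0)
    ranges[ranges == 0] = 1.0
    return X, labels, ranges, is_numeric


def _has_meta(table: CohortTable, name: str) -> bool:
    try:
        table.meta_for(name)
        return True
    except KeyError:
        return False


def relieff_weights(
    table: CohortTable,
    features: list[str] | None = None,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Canonical ReliefF weights for every feature at once.

    ``m`` is the number of probe instances (default: all instances, a
    deterministic exhaustive pass).  ``k`` nearest hits/misses; a class
    with fewer members reduces k for that class with a warning.  The
    per-feature difference is an inequality indicator for discrete
    features and ``|a - b| / range`` for numeric ones; distances between
    instances use the same diffs summed over all features.
    """
    features = features if features is not None else table.feature_names
    X, labels, ranges, is_numeric = _relieff_prepare(table, features)
    n, p = X.shape
    classes, class_counts = np.unique(labels, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, class_counts)}
    if (class_counts < k + 1).any():
        warnings.warn("class smaller than k+1: k reduced for that class")

    # pairwise per-feature diffs are recomputed per probe (n is small)
    def diffs_to(i: int) -> np.ndarray:
        d = np.abs(X - X[i]) / ranges
        d[:, ~is_numeric] = (X[:, ~is_numeric] != X[i, ~is_numeric]).astype(float)
        return d

    if m is None or m >= n:
        probes = np.arange(n)
    else:
        probes = np.random.default_rng(seed).choice(n, size=m, replace=False)
    m_eff = len(probes)

    W = np.zeros(p)
    for i in probes:
        d = diffs_to(i)
        dist = d.sum(axis=1)
        for cls in classes:
            members = np.flatnonzero((labels == cls) & (np.arange(n) != i))
            if members.size == 0:
                continue
            kk = min(k, members.size)
            nearest = members[np.argsort(dist[members], kind="stable")[:kk]]
            mean_diff = d[nearest].mean(axis=0)
            if cls == labels[i]:
                W -= mean_diff / m_eff
            else:
                W += (priors[cls] / (1.0 - priors[labels[i]])) * mean_diff / m_eff
    return pd.Series(W, index=features)


def relieff_score(
    table: CohortTable, feature: str, k: int = 10, m: int | None = None, seed: int = 0
) -> float:
    """ReliefF weight of a single feature (computed jointly over the
    table's features, as the distance metric requires)."""
    return float(relieff_weights(table, k=k, m=m, seed=seed)[feature])


# ---------------------------------------------------------------------------
# Ranking over a table


def discretize_numeric(
    feature: pd.Series, bins: int = 5
) -> pd.Series:
    """Equal-frequency binning of a numeric column (missing preserved)."""
    observed = feature.dropna()
    if observed.nunique() <= bins:
        return feature
    binned = pd.qcut(observed, q=bins, duplicates="drop", labels=False)
    out = pd.Series(np.nan, index=feature.index, dtype=float)
    out.loc[binned.index] = binned.astype(float)
    return out


@dataclass
class RankerScores:
    """Weights assigned to every feature by one ranking method."""

    method: str
    weights: pd.Series

    def ranked(self) -> list[str]:
        """Feature names by descending weight; ties broken by original
        column order (stable)."""
        order = np.argsort(-self.weights.to_numpy(), kind="stable")
        return [self.weights.index[i] for i in order]


@dataclass
class ContributionProfile:
    """Ensemble percentage contributions (sum to 100) plus the
    per-method normalized views they were averaged from."""

    contributions: pd.Series          # feature -> percentage, sums to 100
    per_method_share: pd.DataFrame    # method x feature, rows sum to 1
    per_method_minmax: pd.DataFrame   # method x feature, min-max scale [0, 1]


def rank_features(
    table: CohortTable,
    methods: tuple[str, ...] = METHODS,
    discretize_bins: int = 5,
    relieff_k: int = 10,
    relieff_m: int | None = None,
    seed: int = 0,
    features: list[str] | None = None,
) -> list[RankerScores]:
    """Score every feature with each requested method.

    Numeric features are equal-frequency binned for the
    contingency/entropy statistics; ReliefF works on raw values.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    features = features if features is not None else table.feature_names
    label = table.label

    disc: dict[str, pd.Series] = {}
    for name in features:
        col = table.data[name]
        kind = table.meta_for(name).kind if _has_meta(table, name) else "numeric"
        disc[name] = discretize_numeric(col, discretize_bins) if kind == "numeric" else col

    chi = pd.Series(
        {f: chi_square_score(ContingencyTable.from_columns(disc[f], label)) for f in features}
    )
    ig = pd.Series({f: information_gain_score(disc[f], label) for f in features})

    results: list[RankerScores] = []
    for method in methods:
        if method == "chi2":
            w = chi
        elif method == "info_gain":
            w = ig
        elif method == "gain_ratio":
            w = pd.Series({f: gain_ratio_score(disc[f], label) for f in features})
        elif method == "sym_uncertainty":
            w = pd.Series({f: symmetrical_uncertainty_score(disc[f], label) for f in features})
        elif method == "relieff":
            w = relieff_weights(table, features, k=relieff_k, m=relieff_m, seed=seed)
        elif method == "least_loss":
            w = pd.Series(
                {f: least_loss_score(ContingencyTable.from_columns(disc[f], label)) for f in features}
            )
        else:  # variable_analysis
            chi_n, ig_n = _minmax(chi), _minmax(ig)
            w = pd.Series(
                {f: variable_analysis_score(chi_n[f], ig_n[f]) for f in features}
            )
        results.append(RankerScores(method=method, weights=w.reindex(features)))
    return results


def _minmax(w: pd.Series) -> pd.Series:
    lo, hi = w.min(), w.max()
    if hi == lo:
        return pd.Series(np.full(len(w), np.nan), index=w.index)
    return (w - lo) / (hi - lo)


def aggregate_contributions(scores: list[RankerScores]) -> ContributionProfile:
    """Average normalized per-method weights into percentage contributions.

    Per method: weights are min-max normalized to [0, 1] (this also
    shifts any negative ReliefF weights to zero) and rescaled to unit
    sum; the contribution of a feature is 100 x the mean share across
    methods.  A method assigning equal weight to every feature
    contributes uniform shares, with a warning.
    """
    if not scores:
        raise ValueError("need at least one method's scores")
    index = scores[0].weights.index
    shares, minmaxed = {}, {}
    for rs in scores:
        if not rs.weights.index.equals(index):
            raise ValueError("all methods must cover the identical feature set")
        mm = _minmax(rs.weights)
        if mm.isna().all():
            warnings.warn(f"{rs.method}: all-equal weights, using uniform shares")
            mm = pd.Series(np.full(len(index), 1.0), index=index)
        minmaxed[rs.method] = mm
        shares[rs.method] = mm / mm.sum()
    share_df = pd.DataFrame(shares).T.reindex(columns=index)
    mm_df = pd.DataFrame(minmaxed).T.reindex(columns=index)
    contributions = 100.0 * share_df.mean(axis=0)
    return ContributionProfile(
        contributions=contributions, per_method_share=share_df, per_method_minmax=mm_df
    )


def select_features(
    profile: ContributionProfile,
    threshold: float = 5.0,
    exclude: list[str] | None = None,
) -> list[str]:
    """Shortlist features scoring at least ``threshold`` (on the 0-100
    min-max scale) under *every* method, drop the ``exclude`` list, and
    return the survivors by descending overall contribution.

    Raises if nothing survives, prompting a threshold change.
    """
    exclude = set(exclude or [])
    mm_pct = 100.0 * profile.per_method_minmax
    passing = mm_pct.columns[(mm_pct >= threshold).all(axis=0)]
    kept = [f for f in passing if f not in exclude]
    if not kept:
        raise ValueError("no features pass the contribution threshold; lower it")
    contrib = profile.contributions
    order = np.argsort(-contrib.loc[kept].to_numpy(), kind="stable")
    return [kept[i] for i in order]
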