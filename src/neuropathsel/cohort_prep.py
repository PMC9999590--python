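"""Cohort data model, recoding, filtering, balancing, splitting and the
Spearman redundancy screen.

The central container is :class:`CohortTable`, a thin wrapper around a
pandas DataFrame (subjects x features, ``NaN`` marking a missing cell)
plus per-feature metadata.  Ordinal staging features are stored as integer
codes in their stated level order; binary presence/absence features as
0/1; the dementia label lives in the ``dementia_status`` column with
values 1 (dementia), 0 (no dementia) or ``NaN`` (status unknown).

All row-level operations (label filtering, complete-case filtering,
class balancing, train/test splitting) only change row membership and
order -- they never alter cell values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LABEL_COLUMN = "dementia_status"

__all__ = [
    "LABEL_COLUMN",
    "FeatureSpec",
    "CohortTable",
    "filter_missing_labels",
    "zscore_by_sex",
    "complete_case_filter",
    "drop_high_missingness",
    "balance_classes",
    "split_train_test",
    "spearman_matrix",
    "read_cohort",
    "write_cohort",
]


@dataclass
class FeatureSpec:
    """Description of a single cohort feature.

    Parameters
    ----------
    name:
        Column name.
    kind:
        ``"nominal"`` (unordered categories, binaries coded 0/1),
        ``"ordinal"`` (ordered integer stage codes) or ``"numeric"``.
    levels:
        Ordered category codes for nominal/ordinal features, or the
        ``(low, high)`` range bounds for numeric features.
    missing_rate:
        Fraction of subjects with the value unrecorded, in [0, 1].
    effect_size:
        Log-odds-style shift of the feature's latent score per unit of
        dementia liability; 0 means uninformative.
    block:
        Optional identifier grouping features generated from a shared
        latent factor (e.g. ``"CAA"``, ``"TSA"``, ``"microinfarct"``).
    """

    name: str
    kind: str
    levels: Sequence[float] = field(default_factory=list)
    missing_rate: float = 0.0
    effect_size: float = 0.0
    block: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"nominal", "ordinal", "numeric", "binary_label"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate outside [0, 1]")
        if self.kind == "numeric":
            lo, hi = self.levels
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{self.name}: numeric bounds must be finite, lo < hi")
        elif self.kind == "ordinal":
            lv = list(self.levels)
            if lv != sorted(lv) or len(set(lv)) != len(lv):
                raise ValueError(f"{self.name}: ordinal levels must be strictly ordered")


@dataclass
class CohortTable:
    """Subjects x features table with missingness and feature metadata."""

    data: pd.DataFrame
    feature_meta: list[FeatureSpec]

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        """All feature columns, label excluded."""
        return [c for c in self.data.columns if c != LABEL_COLUMN]

    @property
    def label(self) -> pd.Series:
        return self.data[LABEL_COLUMN]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def meta_for(self, name: str) -> FeatureSpec:
        for spec in self.feature_meta:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data=data, feature_meta=self.feature_meta)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.feature_meta))


# ---------------------------------------------------------------------------
# Row-level filters


def filter_missing_labels(table: CohortTable) -> CohortTable:
    """Drop subjects whose dementia status is unknown, preserving order."""
    keep = table.label.notna()
    return table.with_data(table.data.loc[keep])


def complete_case_filter(table: CohortTable, features: Iterable[str]) -> CohortTable:
    """Retain subjects with no missing value among ``features``."""
    features = list(features)
    if not features:
        return table.with_data(table.data)
    keep = table.data[features].notna().all(axis=1)
    return table.with_data(table.data.loc[keep])


def drop_high_missingness(
    table: CohortTable, candidates: Iterable[str], threshold: float = 0.45
) -> list[str]:
    """Return ``candidates`` minus features whose empirical missingness
    exceeds ``threshold`` (fraction of rows currently in the table)."""
    out = []
    for name in candidates:
        rate = table.data[name].isna().mean()
        if rate <= threshold:
            out.append(name)
    return out


def balance_classes(table: CohortTable, seed: int) -> CohortTable:
    """Downsample the majority class to the minority size and shuffle rows.

    Sampling is uniform without replacement and fully determined by
    ``seed``.
    """
    labels = table.label
    counts = labels.value_counts()
    if len(counts) != 2 or (counts == 0).any():
        raise ValueError("balance_classes requires two non-empty classes")
    rng = np.random.default_rng(seed)
    minority_n = counts.min()
    kept_idx: list = []
    for value in sorted(counts.index):
        members = labels.index[labels == value].to_numpy()
        if len(members) > minority_n:
            members = rng.choice(members, size=minority_n, replace=False)
        kept_idx.extend(members.tolist())
    order = rng.permutation(len(kept_idx))
    shuffled = [kept_idx[i] for i in order]
    return table.with_data(table.data.loc[shuffled])


def split_train_test(
    table: CohortTable, train_fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive random split.

    The training size is round-half-up of ``n * train_fraction`` (so 114
    subjects at 0.7 give an 80/34 split).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = table.n_subjects
    n_train = int(math.floor(n * train_fraction + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_rows = table.data.iloc[order[:n_train]]
    test_rows = table.data.iloc[order[n_train:]]
    return table.with_data(train_rows), table.with_data(test_rows)


# ---------------------------------------------------------------------------
# Recoding


def zscore_by_sex(table: CohortTable, feature: str, group: str) -> CohortTable:
    """Z-score ``feature`` within each level of ``group``.

    Observed values are replaced by ``(x - group mean) / group SD``
    (population SD of the observed values in that group); missing cells
    are untouched.  A group level with zero variance raises an error
    naming the level.
    """
    data = table.data.copy()
    col = data[feature]
    for level, members in data.groupby(group, dropna=True).groups.items():
        vals = col.loc[members]
        observed = vals.dropna()
        if observed.empty:
            continue
        sd = observed.std(ddof=0)
        if len(observed) > 1 and sd == 0:
            raise ValueError(f"zero variance in {feature!r} for {group}={level!r}")
        if len(observed) == 1:
            data.loc[observed.index, feature] = 0.0
        else:
            data.loc[observed.index, feature] = (observed - observed.mean()) / sd
    return table.with_data(data)


# ---------------------------------------------------------------------------
# Redundancy screen


def spearman_matrix(
    table: CohortTable,
    features: Sequence[str] | None = None,
    threshold: float = 0.7,
    min_periods: int = 3,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Pairwise-complete Spearman correlation matrix plus redundancy clusters.

    Ties are handled by midranks.  Pairs with fewer than ``min_periods``
    complete observations are reported as ``NaN`` (undefined).  The second
    return value lists the connected components (size >= 2) of the graph
    linking features with ``|rho| > threshold``.
    """
    names = list(features) if features is not None else table.feature_names
    if len(names) < 2:
        raise ValueError("spearman_matrix needs at least two features")
    sub = table.data[names].astype(float)
    rho = sub.corr(method="spearman", min_periods=min_periods)
    np.fill_diagonal(rho.values, 1.0)

    # connected components over |rho| > threshold
    adjacency = {n: set() for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = rho.loc[a, b]
            if pd.notna(r) and abs(r) > threshold:
                adjacency[a].add(b)
                adjacency[b].add(a)
    seen: set[str] = set()
    clusters: list[list[str]] = []
    for name in names:
        if name in seen or not adjacency[name]:
            continue
        comp, frontier = [], [name]
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            frontier.extend(adjacency[node] - seen)
        if len(comp) >= 2:
            clusters.append(sorted(comp))
    return rho, clusters


# ---------------------------------------------------------------------------
# I/O: CSV table + JSON metadata sidecar


def write_cohort(table: CohortTable, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the cohort as CSV (empty cell = missing) plus a JSON sidecar
    with the feature metadata."""
    csv_path = Path(csv_path)
    table.data.to_csv(csv_path, index_label="subject_id")
    if meta_path is None:
        meta_path = csv_path.with_suffix(".schema.json")
    payload = [asdict(spec) for spec in table.feature_meta]
    Path(meta_path).write_text(json.dumps(payload, indent=1))


def read_cohort(csv_path: str | Path, meta_path: str | Path | None = None) -> CohortTable:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".schema.json")
    data = pd.read_csv(csv_path, index_col="subject_id")
    meta = [FeatureSpec(**d) for d in json.loads(Path(meta_path).read_text())]
    return CohortTable(data=data, feature_meta=meta)


def point_biserial(feature: pd.Series, label: pd.Series) -> float:
    """Point-biserial correlation between a feature and the binary label,
    over pairwise-complete observations (diagnostic helper)."""
    ok = feature.notna() & label.notna()
    x, y = feature[ok].astype(float), label[ok].astype(float)
    if x.nunique() < 2 or y.nunique() < 2:
        return 0.0
    return float(stats.pointbiserialr(y, x).correlation)
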