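"""End-to-end pipeline: cohort -> ranking -> benchmark -> consensus
clustering -> signatures -> combined re-evaluation.

Every stage writes its artifact (TSV/JSON tables, PNG figures) under an
output directory, mirroring how the analysis would be run on a real
cohort export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import cohort_prep, feature_ranking
from .classification_bench import (
    MetricSet,
    SweepResult,
    build_subsets,
    default_classifier_specs,
    evaluate_subsets,
)
from .cohort_prep import CohortTable, write_cohort
from .misclassification_consensus import (
    cluster_feature_ttests,
    cluster_outcomes,
    loocv_outcomes,
    misclassification_rate,
    outcome_fractions,
)
from .signature_explanation import (
    choose_signature,
    combined_feature_eval,
    signature_curve,
    subsample_stability,
)
from .synthetic_cohort import NONSTANDARD_FEATURES, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _json_default(obj):
    if isinstance(obj, MetricSet):
        return obj.as_dict()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(type(obj))


def _dump(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_json_default))


def plot_sweep(sweep: SweepResult, metric: str, path: Path) -> None:
    """Metric-vs-subset-size curves, one line per classifier."""
    fig, ax = plt.subplots(figsize=(7, 4))
    t = sweep.table
    for clf, grp in t[t.metric == metric].groupby("classifier"):
        grp = grp.sort_values("subset_size")
        ax.plot(grp.subset_size, grp["mean"], marker="o", ms=3, label=clf)
    ax.set_xlabel("feature subset size")
    ax.set_ylabel(f"mean {metric}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_outcome_heatmap(correctness: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(correctness.to_numpy(), aspect="auto", cmap="RdYlGn", vmin=0, vmax=1)
    ax.set_xlabel("classifier x subset runs")
    ax.set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(
    out_dir: str | Path,
    config: CohortConfig | None = None,
    seed: int = 0,
    repeats: int = 500,
    rfe_subsamples: int = 100,
    contribution_threshold: float = 5.0,
    missingness_drop_threshold: float = 0.45,
    classifiers: tuple[str, ...] | None = None,
    n_classical_top: int = 8,
    cohort: CohortTable | None = None,
    make_plots: bool = True,
) -> dict:
    """Run the whole analysis on a (by default synthetic) cohort and
    write every artifact under ``out_dir``.

    Returns a summary dict of the headline quantities: sample counts at
    each filtering stage, the number of selected features, the best
    mean F1 over subsets, the consensus misclassification percentages
    (classical, combined, age-stratified), per-cluster signatures and
    the holdout metric contrast.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    # --- cohort ---------------------------------------------------------
    if cohort is None:
        config = config or CohortConfig(seed=rng_seed)
        cohort = generate_cohort(config, seed=rng_seed)
    write_cohort(cohort, out / "cohort.csv")
    summary: dict = {"n_total": cohort.n_subjects}

    # --- preparation ----------------------------------------------------
    labeled = cohort_prep.filter_missing_labels(cohort)
    summary["n_labeled"] = labeled.n_subjects
    if "brain_weight" in labeled.data.columns and "gender" in labeled.data.columns:
        labeled = cohort_prep.zscore_by_sex(labeled, "brain_weight", "gender")

    rho, redundancy_clusters = cohort_prep.spearman_matrix(labeled)
    rho.to_csv(out / "spearman_matrix.tsv", sep="\t")
    _dump(redundancy_clusters, out / "redundancy_clusters.json")

    # --- ranking --------------------------------------------------------
    ranking_pool = [f for f in labeled.feature_names if f not in NONSTANDARD_FEATURES]
    ranking_pool += [f for f in ("age", "brain_weight") if f in labeled.data.columns]
    scores = feature_ranking.rank_features(labeled, features=ranking_pool, seed=rng_seed)
    weight_table = pd.DataFrame({rs.method: rs.weights for rs in scores})
    weight_table.to_csv(out / "rank_weights.tsv", sep="\t")
    profile = feature_ranking.aggregate_contributions(scores)
    profile.contributions.sort_values(ascending=False).to_csv(
        out / "contributions.tsv", sep="\t", header=["contribution_pct"]
    )
    _dump(profile.contributions.to_dict(), out / "contributions.json")

    shortlist = feature_ranking.select_features(profile, threshold=contribution_threshold)
    summary["n_shortlist"] = len(shortlist)
    high_missing = set(shortlist) - set(
        cohort_prep.drop_high_missingness(labeled, shortlist, missingness_drop_threshold)
    )
    exclude = {"age", "brain_weight"} | high_missing
    selected = [f for f in shortlist if f not in exclude]
    _dump({"shortlist": shortlist, "excluded": sorted(exclude & set(shortlist)),
           "selected": selected}, out / "selected_features.json")
    summary["n_selected"] = len(selected)

    # --- balancing, split, holdout -------------------------------------
    complete = cohort_prep.complete_case_filter(labeled, selected)
    summary["n_complete"] = complete.n_subjects
    balanced = cohort_prep.balance_classes(complete, seed=rng_seed)
    summary["n_balanced"] = balanced.n_subjects
    holdout_ids = complete.subject_ids.difference(balanced.subject_ids)
    holdout = complete.with_data(complete.data.loc[holdout_ids])
    summary["n_holdout"] = holdout.n_subjects
    train, test = cohort_prep.split_train_test(balanced, 0.7, seed=rng_seed)
    summary["n_train"], summary["n_test"] = train.n_subjects, test.n_subjects

    spec_names = classifiers or None
    specs = default_classifier_specs(spec_names) if spec_names else default_classifier_specs()
    _dump({s.name: {k: repr(v) for k, v in s.resolved_hyperparameters().items()}
           for s in specs}, out / "classifier_config.json")

    # --- stepwise benchmark --------------------------------------------
    subsets_fwd = build_subsets(selected, "forward")
    subsets_bwd = build_subsets(selected, "backward")
    sweep_parts = []
    for direction, subsets in (("forward", subsets_fwd), ("backward", subsets_bwd)):
        sw = evaluate_subsets(
            balanced, subsets, specs, train_fraction=0.7, repeats=repeats,
            seed=rng_seed, direction=direction,
        )
        sweep_parts.append(sw.table)
    sweep = SweepResult(table=pd.concat(sweep_parts, ignore_index=True), repeats=repeats)
    sweep.to_tsv(out / "sweep.tsv")
    _dump(sweep.table.to_dict(orient="records"), out / "sweep.json")
    if make_plots:
        for metric in ("f1", "accuracy", "balanced_accuracy", "sensitivity", "specificity"):
            plot_sweep(sweep, metric, out / f"sweep_{metric}.png")

    fwd = sweep.table[(sweep.table.direction == "forward") & (sweep.table.metric == "f1")]
    best = fwd.loc[fwd["mean"].idxmax()]
    summary["best_f1_pct"] = float(100 * best["mean"])
    summary["best_f1_subset_size"] = int(best["subset_size"])
    summary["best_f1_classifier"] = str(best["classifier"])

    # --- consensus misclassification -----------------------------------
    outcome = loocv_outcomes(balanced, subsets_fwd, specs, seed=rng_seed)
    outcome.outcomes.to_csv(out / "outcome_matrix.tsv", sep="\t")
    summary["misclassification_pct"] = misclassification_rate(outcome)
    summary.update(outcome_fractions(outcome))
    assignment = cluster_outcomes(outcome, k=3)
    _dump(assignment.assignment.to_dict(), out / "clusters.json")
    if make_plots:
        plot_outcome_heatmap(outcome.correctness, out / "outcome_heatmap.png")

    nonstandard = [f for f in NONSTANDARD_FEATURES if f in cohort.data.columns]
    cluster_sizes = assignment.assignment.value_counts().to_dict()
    summary["cluster_sizes"] = {str(k): int(v) for k, v in cluster_sizes.items()}
    if {"false_positive", "false_negative"} <= set(cluster_sizes):
        ttests = cluster_feature_ttests(balanced, assignment, nonstandard)
        ttests.to_csv(out / "cluster_ttests.tsv", sep="\t")

    # per-cluster mean feature levels (the descriptive companion table)
    level_rows = {}
    for lab in assignment.assignment.unique():
        ids = assignment.members(lab)
        level_rows[lab] = balanced.data.loc[ids, nonstandard].mean()
    pd.DataFrame(level_rows).to_csv(out / "cluster_feature_means.tsv", sep="\t")

    # --- signatures per cluster ----------------------------------------
    signatures = {}
    for lab in ("correct", "false_positive", "false_negative"):
        target = (assignment.assignment == lab).astype(int)
        counts = target.value_counts()
        if len(counts) < 2 or counts.min() < 5:
            logger.warning("cluster %s too small for signature analysis; skipped", lab)
            continue
        freq = subsample_stability(
            balanced, target, nonstandard, M=rfe_subsamples, seed=rng_seed
        )
        freq.to_csv(out / f"signature_frequency_{lab}.tsv", sep="\t")
        curve = signature_curve(balanced, target, freq, seed=rng_seed)
        sig = choose_signature(curve, cluster=lab)
        signatures[lab] = {
            "features": sig.features,
            "size": sig.size,
            "accuracy": sig.score.accuracy,
            "f1": sig.score.f1,
            "curve": {"sizes": curve.sizes, "accuracy": curve.accuracy,
                      "f1": curve.f1, "f1_se": curve.f1_se},
        }
    _dump(signatures, out / "signatures.json")
    summary["signature_sizes"] = {k: v["size"] for k, v in signatures.items()}

    # --- combined classical + non-standard re-evaluation ----------------
    classical_top = selected[:n_classical_top]
    combined = combined_feature_eval(
        balanced, classical_top, nonstandard, specs, seed=rng_seed, holdout=holdout,
        holdout_spec=next((s for s in specs if s.name == "logistic_regression"), specs[0]),
    )
    _dump(combined, out / "combined_eval.json")
    for key, value in combined.items():
        if isinstance(value, MetricSet):
            summary[f"{key}_sensitivity_pct"] = float(100 * value.sensitivity)
        else:
            summary[key] = value

    _dump(summary, out / "summary.json")
    return summary
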