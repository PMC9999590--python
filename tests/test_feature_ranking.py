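"""The seven filter statistics against independent brute-force oracles,
plus the ensemble aggregation and the contribution-threshold shortlist."""

import math
import warnings
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from neuropathsel import FeatureSpec, generate_cohort
from neuropathsel.feature_ranking import (
    METHODS,
    ContingencyTable,
    RankerScores,
    aggregate_contributions,
    chi_square_score,
    gain_ratio_score,
    information_gain_score,
    least_loss_score,
    rank_features,
    relieff_weights,
    select_features,
    symmetrical_uncertainty_score,
    variable_analysis_score,
)
from neuropathsel.synthetic_cohort import CohortConfig, NONSTANDARD_FEATURES

from conftest import make_table


def series(vals):
    return pd.Series(vals, dtype=float)


def table_from(counts_2x2):
    """ContingencyTable from a 2 (class) x k (level) count matrix."""
    feat, lab = [], []
    for i, row in enumerate(counts_2x2):
        for j, c in enumerate(row):
            feat += [j] * c
            lab += [i] * c
    return ContingencyTable.from_columns(series(feat), series(lab))


# --------------------------------------------------------------------------
# independent oracles (plain-Python, no reuse of the package's code paths)


def oracle_entropy(values):
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in Counter(values).values())


def oracle_ig(feature, label):
    pairs = list(zip(feature, label))
    total = oracle_entropy(label)
    cond = 0.0
    for v in set(feature):
        sub = [l for f, l in pairs if f == v]
        cond += len(sub) / len(pairs) * oracle_entropy(sub)
    return total - cond


def oracle_chi2(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def oracle_least_loss(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            total += (counts[i, j] / n - counts[i].sum() / n * counts[:, j].sum() / n) ** 2
    return total


def random_discrete_columns(rng, n, k_feat=3):
    feature = rng.integers(0, k_feat, size=n)
    label = rng.integers(0, 2, size=n)
    return feature.tolist(), label.tolist()


# --------------------------------------------------------------------------


class TestChiSquare:
    def test_independence_gives_zero(self):
        c = table_from([[20, 20], [10, 10]])
        assert chi_square_score(c) == pytest.approx(0.0, abs=1e-12)

    def test_printed_2x2_example(self):
        assert chi_square_score(table_from([[30, 10], [10, 30]])) == pytest.approx(20.0)

    def test_doubling_counts_doubles_statistic(self):
        a = chi_square_score(table_from([[30, 10], [10, 30]]))
        b = chi_square_score(table_from([[60, 20], [20, 60]]))
        assert b == pytest.approx(2 * a)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            feat, lab = random_discrete_columns(rng, 12)
            c = ContingencyTable.from_columns(series(feat), series(lab))
            if len(set(lab)) < 2 or len(set(feat)) < 2:
                continue
            counts = pd.crosstab(series(lab), series(feat)).to_numpy()
            assert chi_square_score(c) == pytest.approx(oracle_chi2(counts), abs=1e-9)

    def test_empty_level_dropped_with_warning(self):
        c = ContingencyTable(observed=np.array([[5.0, 0.0], [5.0, 0.0]]), n=10)
        with pytest.warns(UserWarning):
            assert chi_square_score(c) == pytest.approx(0.0)


class TestInformationGain:
    def test_feature_identical_to_balanced_label_is_one_bit(self):
        f = series([0, 0, 1, 1]); l = series([0, 0, 1, 1])
        assert information_gain_score(f, l) == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        assert information_gain_score(series([2, 2, 2, 2]), series([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_eight_sample_split_example(self):
        # two-level feature with class splits (3,1) and (1,3)
        f = series([0, 0, 0, 0, 1, 1, 1, 1])
        l = series([1, 1, 1, 0, 0, 0, 0, 1])
        expected = 1.0 - (0.5 * oracle_entropy([1, 1, 1, 0]) + 0.5 * oracle_entropy([0, 0, 0, 1]))
        assert information_gain_score(f, l) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.18872187554086717)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            feat, lab = random_discrete_columns(rng, 12)
            got = information_gain_score(series(feat), series(lab))
            assert got == pytest.approx(oracle_ig(feat, lab), abs=1e-9)


class TestGainRatio:
    def test_feature_identical_to_balanced_label_is_one(self):
        f = series([0, 1, 0, 1]); l = series([0, 1, 0, 1])
        assert gain_ratio_score(f, l) == pytest.approx(1.0)

    def test_constant_feature_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert gain_ratio_score(series([3, 3, 3]), series([0, 1, 0])) == 0.0

    def test_equals_ig_over_feature_entropy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            feat, lab = random_discrete_columns(rng, 12)
            if len(set(feat)) < 2:
                continue
            expected = oracle_ig(feat, lab) / oracle_entropy(feat)
            assert gain_ratio_score(series(feat), series(lab)) == pytest.approx(expected, abs=1e-12)


class TestSymmetricalUncertainty:
    def test_identical_feature_is_one(self):
        f = series([0, 1, 1, 0]); l = series([0, 1, 1, 0])
        assert symmetrical_uncertainty_score(f, l) == pytest.approx(1.0)

    def test_independent_feature_is_zero(self):
        f = series([0, 0, 1, 1]); l = series([0, 1, 0, 1])
        assert symmetrical_uncertainty_score(f, l) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_and_relabel_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            feat, lab = random_discrete_columns(rng, 12)
            su = symmetrical_uncertainty_score(series(feat), series(lab))
            assert -1e-12 <= su <= 1 + 1e-12
            relabeled = [{0: 7, 1: 5, 2: 9}[f] for f in feat]
            assert symmetrical_uncertainty_score(series(relabeled), series(lab)) == pytest.approx(su)


def oracle_relieff(X, y, k):
    """Hand simulation of the exhaustive ReliefF pass (nominal diffs)."""
    n, p = X.shape
    W = np.zeros(p)
    priors = {c: (y == c).mean() for c in np.unique(y)}
    for i in range(n):
        diffs = (X != X[i]).astype(float)
        dist = diffs.sum(axis=1)
        for c in np.unique(y):
            members = [j for j in range(n) if j != i and y[j] == c]
            if not members:
                continue
            members.sort(key=lambda j: (dist[j], j))
            near = members[: min(k, len(members))]
            md = diffs[near].mean(axis=0)
            if c == y[i]:
                W -= md / n
            else:
                W += priors[c] / (1 - priors[y[i]]) * md / n
    return W


class TestReliefF:
    def test_constant_feature_is_zero(self):
        t = make_table({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]}, [0, 0, 1, 1])
        w = relieff_weights(t, k=1)
        assert w["a"] == pytest.approx(0.0)

    def test_perfect_separator_scores_plus_one(self):
        t = make_table({"a": [0, 0, 1, 1]}, [0, 0, 1, 1])
        w = relieff_weights(t, k=1)
        assert w["a"] == pytest.approx(1.0)

    def test_matches_hand_simulation_on_small_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 8
            cols = {f"f{j}": rng.integers(0, 3, size=n).tolist() for j in range(3)}
            labels = rng.integers(0, 2, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            t = make_table(cols, labels.tolist())
            got = relieff_weights(t, k=2)
            X = np.column_stack([cols[f"f{j}"] for j in range(3)])
            expected = oracle_relieff(X, labels, k=2)
            np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-6)

    def test_pure_noise_feature_has_near_zero_mean_weight(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = make_table(
                {"noise": rng.integers(0, 2, size=20).tolist()},
                [0, 1] * 10,
            )
            vals.append(relieff_weights(t, k=3)["noise"])
        assert abs(np.mean(vals)) < 0.1


class TestLeastLoss:
    def test_independent_feature_is_zero(self):
        assert least_loss_score(table_from([[20, 20], [10, 10]])) == pytest.approx(0.0, abs=1e-15)

    def test_printed_joint_example(self):
        # joint [[0.4, 0.1], [0.1, 0.4]]: four deviations of 0.15 each
        c = table_from([[40, 10], [10, 40]])
        assert least_loss_score(c) == pytest.approx(0.09)

    def test_class_swap_invariant(self):
        a = least_loss_score(table_from([[30, 10], [5, 25]]))
        b = least_loss_score(table_from([[5, 25], [30, 10]]))
        assert a == pytest.approx(b)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            feat, lab = random_discrete_columns(rng, 12)
            c = ContingencyTable.from_columns(series(feat), series(lab))
            counts = pd.crosstab(series(lab), series(feat)).to_numpy()
            assert least_loss_score(c) == pytest.approx(oracle_least_loss(counts), abs=1e-12)


class TestVariableAnalysis:
    @pytest.mark.parametrize(
        "chi_n,ig_n,expected",
        [(0.0, 0.0, 0.0), (1.0, 1.0, math.sqrt(2)), (0.3, 0.4, 0.5)],
    )
    def test_vector_magnitude(self, chi_n, ig_n, expected):
        assert variable_analysis_score(chi_n, ig_n) == pytest.approx(expected)


class TestRankFeatures:
    def test_default_run_ranks_36_features(self, labeled_cohort):
        pool = [f for f in labeled_cohort.feature_names if f not in NONSTANDARD_FEATURES]
        pool += ["age", "brain_weight"]
        assert len(pool) == 36
        scores = rank_features(labeled_cohort, features=pool, seed=0)
        assert len(scores) == 7
        for rs in scores:
            assert len(rs.weights) == 36

    def test_single_feature_table_ranks_it_first(self):
        t = make_table({"only": [0, 0, 1, 1, 0, 1]}, [0, 0, 1, 1, 0, 1])
        for rs in rank_features(t, seed=0):
            assert rs.ranked()[0] == "only"

    def test_single_planted_effect_recovered_by_entropy_methods(self):
        # one strong planted feature among nine null features
        schema = [FeatureSpec("planted", "ordinal", list(range(5)), 0.0, 1.5)]
        schema += [FeatureSpec(f"null{i}", "ordinal", list(range(4)), 0.0, 0.0) for i in range(9)]
        schema.append(FeatureSpec("dementia_status", "binary_label", [0, 1]))
        hits = 0
        for seed in range(20):
            t = generate_cohort(CohortConfig(features=schema), seed=seed)
            scores = rank_features(
                t, methods=("info_gain", "gain_ratio", "sym_uncertainty"), seed=seed
            )
            if all(rs.ranked().index("planted") < 3 for rs in scores):
                hits += 1
        assert hits >= 18


class TestAggregation:
    def test_single_method_shares_scale_to_percentages(self):
        rs = RankerScores("chi2", pd.Series({"a": 5.0, "b": 3.0, "c": 2.0, "d": 0.0}))
        profile = aggregate_contributions([rs])
        # min-max of (5,3,2,0) is (1,.6,.4,0); unit-sum shares (.5,.3,.2,0)
        assert profile.contributions.to_dict() == pytest.approx(
            {"a": 50.0, "b": 30.0, "c": 20.0, "d": 0.0}
        )

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = [
                RankerScores(m, pd.Series(rng.normal(size=8), index=list("abcdefgh")))
                for m in METHODS[:4]
            ]
            total = aggregate_contributions(scores).contributions.sum()
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_method_order_invariant_and_feature_equivariant(self):
        rng = np.random.default_rng(7)
        w1 = pd.Series(rng.random(6), index=list("abcdef"))
        w2 = pd.Series(rng.random(6), index=list("abcdef"))
        fwd = aggregate_contributions([RankerScores("chi2", w1), RankerScores("info_gain", w2)])
        rev = aggregate_contributions([RankerScores("info_gain", w2), RankerScores("chi2", w1)])
        pd.testing.assert_series_equal(fwd.contributions, rev.contributions)
        perm = list("fedcba")
        permuted = aggregate_contributions(
            [RankerScores("chi2", w1[perm]), RankerScores("info_gain", w2[perm])]
        )
        assert permuted.contributions["a"] == pytest.approx(fwd.contributions["a"])

    def test_opposite_orderings_average_like_brute_force(self):
        up = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        down = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        profile = aggregate_contributions(
            [RankerScores("chi2", up), RankerScores("info_gain", down)]
        )
        # brute force: each method min-max -> (0,.5,1)/(1,.5,0); shares
        # (0,1/3,2/3)/(2/3,1/3,0); mean share is 1/3 each
        assert profile.contributions.to_dict() == pytest.approx(
            {"a": 100 / 3, "b": 100 / 3, "c": 100 / 3}
        )

    def test_all_equal_weights_fall_back_to_uniform(self):
        with pytest.warns(UserWarning):
            profile = aggregate_contributions(
                [RankerScores("chi2", pd.Series([2.0, 2.0], index=list("ab")))]
            )
        assert profile.contributions.to_dict() == pytest.approx({"a": 50.0, "b": 50.0})


class TestSelectFeatures:
    def _profile(self, n=25, seed=0):
        rng = np.random.default_rng(seed)
        names = ["age", "brain_weight", "hippocampal_tau_nft_stage"] + [
            f"f{i}" for i in range(n - 3)
        ]
        scores = [
            RankerScores(m, pd.Series(rng.random(n) + 0.2, index=names)) for m in METHODS[:3]
        ]
        return aggregate_contributions(scores)

    def test_paper_shaped_shortlist_arithmetic(self):
        profile = self._profile()
        out = select_features(
            profile, threshold=0.0,
            exclude=["age", "brain_weight", "hippocampal_tau_nft_stage"],
        )
        assert len(out) == 22

    def test_threshold_zero_returns_all_sorted(self):
        profile = self._profile()
        out = select_features(profile, threshold=0.0)
        assert len(out) == 25
        contribs = profile.contributions[out].to_numpy()
        assert (np.diff(contribs) <= 1e-12).all()

    def test_threshold_above_max_raises(self):
        with pytest.raises(ValueError):
            select_features(self._profile(), threshold=101.0)
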