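import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from dvos.stats import (
    StatsError,
    YoudenThresholdClassifier,
    confusion_metrics,
    roc_analysis,
    sample_size,
    spearman_screen,
    welch_test,
)


# ---------------------------------------------------------------------------
# Welch t-test

class TestWelch:
    def test_printed_group_summaries(self):
        """Positive 6.7+/-9.3 (n=9) vs negative -7.1+/-4.3 (n=5)."""
        res = welch_test((6.7, 9.3, 9), (-7.1, 4.3, 5))
        assert round(res.t, 2) == -3.78
        assert round(res.df, 1) == 11.8
        assert res.p_adjusted == pytest.approx(0.008, abs=5e-4)

    def test_identical_groups_give_zero_t(self):
        res = welch_test([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert res.t == 0.0
        assert res.df == pytest.approx(4.0)

    def test_matches_scipy_on_raw_values(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 2, 9), rng.normal(-1, 1, 5)
        res = welch_test(a, b)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_bonferroni_caps_at_one(self):
        res = welch_test([0.0, 1.0], [0.1, 0.9], bonferroni_m=100)
        assert res.p_adjusted == 1.0
        assert res.p_adjusted == min(1.0, res.bonferroni_m * res.p_raw)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_antisymmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 4)
        fwd, rev = welch_test(a, b), welch_test(b, a)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)
        assert fwd.df == pytest.approx(rev.df, abs=1e-12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(StatsError):
            welch_test([1.0], [2.0, 3.0])
        with pytest.raises(StatsError):
            welch_test((1.0, 0.0, 5), (2.0, 0.0, 5))


# ---------------------------------------------------------------------------
# Spearman screen

class TestSpearmanScreen:
    def test_monotone_pair_flagged(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40]})
        screen = spearman_screen(df)
        assert screen.correlation.loc["x", "y"] == pytest.approx(1.0)
        assert [(a, b) for a, b, _ in screen.flagged_pairs] == [("x", "y")]

    def test_antitone_pair_not_flagged(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]})
        screen = spearman_screen(df)
        assert screen.correlation.loc["x", "y"] == pytest.approx(-1.0)
        assert screen.flagged_pairs == []

    def test_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        # brute force: Pearson correlation of explicit ranks
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        oracle = np.corrcoef(rx, ry)[0, 1]
        screen = spearman_screen(pd.DataFrame({"x": x, "y": y}))
        assert screen.correlation.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_reported_undefined(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        screen = spearman_screen(df)
        assert np.isnan(screen.correlation.loc["x", "y"])

    def test_pairwise_complete_with_missing(self):
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [2, 4, 6, 8, 10.0]}
        )
        screen = spearman_screen(df)
        assert screen.correlation.loc["x", "y"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ROC / Youden

def brute_force_auc(scores, labels):
    """Exhaustive positive/negative pair counting, ties worth one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive search over all midpoint thresholds for max J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    mids = np.concatenate(([-np.inf], (distinct[1:] + distinct[:-1]) / 2, [np.inf]))
    best = None
    for c in mids:
        pred = scores >= c
        se = (pred & (labels == 1)).sum() / (labels == 1).sum()
        sp = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = se + sp - 1
        key = (j, -((1 - se) ** 2 + (1 - sp) ** 2), c)
        if best is None or key > best:
            best = key
    return best[0], best[2]


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([2.0, 3.0, 4.0, 0.0, 1.0])
        labels = np.array([1, 1, 1, 0, 0])
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0
        i = int(np.argmax(roc.youden_j))
        assert roc.sensitivity[i] == 1.0 and roc.specificity[i] == 1.0
        assert 1.0 < roc.cutoff < 2.0

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        scores = rng.integers(0, 6, n).astype(float)  # forces ties
        labels = np.r_[np.ones(2, int), rng.integers(0, 2, n - 4), np.zeros(2, int)]
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_small_instance_auc_by_hand(self):
        # positives {1,3,4}, negatives {0,2}: 5 wins of 6 pairs
        roc = roc_analysis([1, 3, 4, 0, 2], [1, 1, 1, 0, 0])
        assert roc.auc == pytest.approx(5.0 / 6.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_youden_cutoff_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 13))
        scores = np.round(rng.normal(size=n), 1)
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        roc = roc_analysis(scores, labels)
        j_best, cut_best = brute_force_youden(scores, labels)
        assert np.max(roc.youden_j) == pytest.approx(j_best, abs=1e-12)
        assert roc.cutoff == pytest.approx(cut_best, abs=1e-12)

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        scores = np.array([-3.0, -1.0, 0.5, 2.0, 4.0, -2.0, 1.0])
        labels = np.array([0, 0, 1, 1, 1, 0, 1])
        base = roc_analysis(scores, labels)
        cubed = roc_analysis(scores**3, labels)
        assert cubed.auc == base.auc
        np.testing.assert_array_equal(
            base.predict(scores), cubed.predict(scores**3)
        )

    def test_j_identity_and_one_class_error(self):
        roc = roc_analysis([1.0, 2.0, 3.0], [0, 1, 1])
        np.testing.assert_allclose(
            roc.youden_j, roc.sensitivity + roc.specificity - 1.0
        )
        with pytest.raises(StatsError):
            roc_analysis([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# Confusion metrics

class TestConfusionMetrics:
    def test_perfect_prediction(self):
        cm = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert cm.as_percentages() == {"Se": 100, "Sp": 100, "PPV": 100, "NPV": 100}
        assert cm.misclassified == 0

    def test_all_positive_predictions(self):
        cm = confusion_metrics([1, 1, 1, 1], [1, 0, 1, 0])
        assert cm.specificity == 0.0
        assert cm.ppv == pytest.approx(0.5)  # prevalence

    def test_counts_partition_by_clinical_truth(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 40)
        truth = rng.integers(0, 2, 40)
        cm = confusion_metrics(pred, truth)
        assert cm.tp + cm.fn == int(truth.sum())
        assert cm.tn + cm.fp == int((1 - truth).sum())

    def test_half_up_percentage_rounding(self):
        cm = confusion_metrics([1] * 8 + [0], [1] * 9)
        assert cm.as_percentages()["Se"] == 89  # 8/9 = 88.9

    def test_non_binary_labels_rejected(self):
        with pytest.raises(StatsError):
            confusion_metrics([0, 1, 2], [0, 1, 1])
        with pytest.raises(StatsError):
            confusion_metrics([], [])


# ---------------------------------------------------------------------------
# Sample size

class TestSampleSize:
    def test_one_sd_effect_reproduces_cohort_estimate(self):
        assert sample_size(alpha=0.05, beta=0.04, effect_sd=1.0) == 56

    def test_half_power_closed_form(self):
        # z_{0.5} = 0: per-group ceil(2 * 1.96^2) = 8, total 16
        assert sample_size(alpha=0.05, beta=0.5, effect_sd=1.0) == 16

    def test_two_sd_effect(self):
        assert sample_size(alpha=0.05, beta=0.04, effect_sd=2.0) == 14

    @settings(max_examples=30, deadline=None)
    @given(
        effect=st.floats(0.2, 3.0, allow_nan=False),
        delta=st.floats(0.05, 1.0, allow_nan=False),
    )
    def test_monotone_in_effect_size(self, effect, delta):
        assert sample_size(0.05, 0.2, effect + delta) <= sample_size(0.05, 0.2, effect)

    def test_monotone_in_alpha_and_beta(self):
        assert sample_size(0.01, 0.2, 1.0) >= sample_size(0.05, 0.2, 1.0)
        assert sample_size(0.05, 0.1, 1.0) >= sample_size(0.05, 0.3, 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            sample_size(0.0, 0.2, 1.0)
        with pytest.raises(StatsError):
            sample_size(0.05, 0.2, 0.0)


# ---------------------------------------------------------------------------
# Threshold classifier

class TestYoudenThresholdClassifier:
    def test_fit_predict_and_fitted_attributes(self):
        X = np.array([[6.7], [10.0], [2.0], [-7.1], [-9.0], [-5.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        clf = YoudenThresholdClassifier().fit(X, y)
        assert clf.auc_ == 1.0
        assert -5.0 < clf.cutoff_ < 2.0
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_cutoff_agrees_with_roc_analysis(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 1))
        y = (X[:, 0] + rng.normal(scale=0.5, size=20) > 0).astype(int)
        y[:2] = [0, 1]
        clf = YoudenThresholdClassifier().fit(X, y)
        assert clf.cutoff_ == roc_analysis(X[:, 0], y).cutoff

    def test_clone_and_param_round_trip(self):
        clf = YoudenThresholdClassifier(direction="less")
        assert clone(clf).get_params() == {"direction": "less"}

    def test_class_labels_preserved(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([3, 3, 7, 7])
        clf = YoudenThresholdClassifier().fit(X, y)
        assert set(clf.predict(X)) <= {3, 7}
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_single_feature_enforced(self):
        with pytest.raises(ValueError):
            YoudenThresholdClassifier().fit(np.zeros((4, 2)), [0, 0, 1, 1])
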