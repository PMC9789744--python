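"""Statistical layer: redundancy screen, group comparison, ROC and power.

Small-cohort diagnostic-accuracy toolkit: Spearman rank screen for
redundant features (|pairs with R > 0.75 collapse to one representative),
Welch two-sample t-tests with Bonferroni adjustment, ROC analysis with the
Youden-index cutoff, confusion-matrix accuracy metrics, and a two-sample
normal-approximation sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

SPEARMAN_REDUNDANCY_R = 0.75
DEFAULT_BONFERRONI_M = 3  # the three independent Gen difference features


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spearman redundancy screen

@dataclass
class SpearmanScreen:
    correlation: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float = SPEARMAN_REDUNDANCY_R


def spearman_screen(
    features: pd.DataFrame, threshold: float = SPEARMAN_REDUNDANCY_R
) -> SpearmanScreen:
    """Pairwise-complete Spearman correlations with redundancy flags.

    Pairs with R strictly above ``threshold`` are flagged as carrying
    redundant information.  Pairs with fewer than 3 complete observations
    or a constant member have undefined (NaN) correlation.
    """
    num = features.select_dtypes(include=[np.number])
    corr = num.corr(method="spearman", min_periods=3)
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > threshold:
                flagged.append((a, b, float(r)))
    return SpearmanScreen(correlation=corr, flagged_pairs=flagged, threshold=threshold)


# ---------------------------------------------------------------------------
# Welch t-test

@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    bonferroni_m: int


def _summary(group) -> tuple[float, float, int]:
    if isinstance(group, tuple) and len(group) == 3:
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 1:
        raise StatsError("group values must be one-dimensional")
    if arr.size < 2:
        return float(arr.mean()) if arr.size else float("nan"), float("nan"), int(arr.size)
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def welch_test(
    positive_group,
    negative_group,
    bonferroni_m: int = DEFAULT_BONFERRONI_M,
) -> TTestResult:
    """Welch's unequal-variance t-test between outcome groups.

    Groups may be raw value arrays or ``(mean, sd, n)`` summaries.  The
    statistic is signed as negative-group mean minus positive-group mean
    over the Welch standard error; degrees of freedom follow
    Welch–Satterthwaite and the two-sided p-value is Bonferroni-adjusted
    by ``bonferroni_m``.
    """
    ma, sa, na = _summary(positive_group)
    mb, sb, nb = _summary(negative_group)
    if na < 2 or nb < 2:
        raise StatsError("each group needs at least 2 observations")
    if sa <= 0 and sb <= 0:
        raise StatsError("at least one group must have positive variance")
    va, vb = sa**2 / na, sb**2 / nb
    se = math.sqrt(va + vb)
    t = (mb - ma) / se
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(
        mean_a=ma, sd_a=sa, n_a=na,
        mean_b=mb, sd_b=sb, n_b=nb,
        t=float(t), df=float(df), p_raw=float(p),
        p_adjusted=float(min(1.0, bonferroni_m * p)),
        bonferroni_m=int(bonferroni_m),
    )


# ---------------------------------------------------------------------------
# ROC / Youden

@dataclass
class ROCResult:
    thresholds: np.ndarray        # candidate cutoffs, ascending
    sensitivity: np.ndarray       # Se at each threshold
    specificity: np.ndarray       # Sp at each threshold
    auc: float
    youden_j: np.ndarray
    cutoff: float                 # argmax-J threshold after tie-breaking
    direction: str                # "greater": predict class 1 when score >= cutoff

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if self.direction == "greater":
            return (s >= self.cutoff).astype(int)
        return (s <= self.cutoff).astype(int)


def roc_analysis(scores, labels, direction: str = "greater") -> ROCResult:
    """ROC curve, Mann–Whitney AUC and the Youden-index optimal cutoff.

    ``direction="greater"`` predicts the positive class when the score is
    at or above the cutoff (so low scores predict a negative outcome).
    Candidate cutoffs sit at midpoints between adjacent distinct scores,
    flanked by -inf and +inf.  The optimal cutoff maximizes
    J = Se + Sp - 1; ties are broken by distance to the ideal (0, 1)
    corner of ROC space, then by the larger cutoff.
    """
    if direction not in ("greater", "less"):
        raise StatsError("direction must be 'greater' or 'less'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise StatsError("scores and labels must be equal-length vectors")
    if np.any(~np.isfinite(s)):
        keep = np.isfinite(s)
        s, y = s[keep], y[keep]
    classes = set(np.unique(y).tolist())
    if not classes <= {0, 1} or len(classes) < 2:
        raise StatsError("labels must contain both classes 0 and 1")
    sign = 1.0 if direction == "greater" else -1.0
    z = sign * s
    pos, neg = z[y == 1], z[y == 0]

    # Mann-Whitney probability with ties counted one half
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))

    distinct = np.unique(z)
    mids = (distinct[1:] + distinct[:-1]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    se = np.array([(pos >= c).mean() for c in thresholds])
    sp = np.array([(neg < c).mean() for c in thresholds])
    j = se + sp - 1.0

    dist2 = (1.0 - se) ** 2 + (1.0 - sp) ** 2
    order = sorted(
        range(len(thresholds)),
        key=lambda i: (-j[i], dist2[i], -thresholds[i]),
    )
    best = order[0]
    cutoff = sign * thresholds[best]
    if direction == "less":
        # mirror the grid back to the original score axis
        thresholds, se, sp, j = thresholds[::-1] * sign, se[::-1], sp[::-1], j[::-1]
    return ROCResult(
        thresholds=thresholds,
        sensitivity=se,
        specificity=sp,
        auc=auc,
        youden_j=j,
        cutoff=float(cutoff),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Confusion metrics

def _pct(x: float) -> int | None:
    """Percentage rounded half-up to the nearest integer; None if undefined."""
    if not np.isfinite(x):
        return None
    return int(math.floor(100.0 * x + 0.5))


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn

    def as_percentages(self) -> dict[str, int]:
        return {
            "Se": _pct(self.sensitivity),
            "Sp": _pct(self.specificity),
            "PPV": _pct(self.ppv),
            "NPV": _pct(self.npv),
        }


def confusion_metrics(predicted, clinical) -> ConfusionMetrics:
    """Diagnostic-accuracy metrics of binary predictions vs clinical truth."""
    p = np.asarray(predicted)
    c = np.asarray(clinical)
    if p.shape != c.shape or p.size == 0:
        raise StatsError("predicted and clinical labels must be equal-length, non-empty")
    for arr in (p, c):
        if not set(np.unique(arr).tolist()) <= {0, 1}:
            raise StatsError("labels must be binary 0/1")
    tp = int(((p == 1) & (c == 1)).sum())
    fp = int(((p == 1) & (c == 0)).sum())
    tn = int(((p == 0) & (c == 0)).sum())
    fn = int(((p == 0) & (c == 1)).sum())

    def rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
    )


# ---------------------------------------------------------------------------
# Sample size

def sample_size(alpha: float, beta: float, effect_sd: float) -> int:
    """Total patients for a two-group comparison, normal approximation.

    Per group ``n = ceil(2 (z_{1-alpha/2} + z_{1-beta})^2 / effect^2)``
    with the effect expressed in units of the common standard deviation;
    the returned total is ``2 n``.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise StatsError("alpha and beta must lie in (0, 1)")
    if effect_sd <= 0:
        raise StatsError("effect size must be positive")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(1.0 - beta)
    if not np.isfinite(z):
        raise StatsError("non-finite normal quantile")
    per_group = math.ceil(2.0 * z**2 / effect_sd**2)
    return 2 * per_group


# ---------------------------------------------------------------------------
# Threshold classifier

class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier fitted at the Youden-optimal cutoff.

    ``fit`` runs a ROC analysis of the lone feature against the binary
    outcome and stores the cutoff maximizing J = Se + Sp - 1; ``predict``
    thresholds new scores at that cutoff.

    Parameters
    ----------
    direction : {"greater", "less"}, default "greater"
        With "greater", scores at or above the cutoff predict class 1
        (so a feature value below the cutoff predicts a negative outcome).

    Attributes
    ----------
    cutoff_ : float
        Youden-optimal decision threshold, in feature units.
    auc_ : float
        Mann–Whitney area under the ROC curve.
    roc_ : ROCResult
        Full ROC grid used for cutoff selection.
    """

    def __init__(self, direction: str = "greater") -> None:
        self.direction = direction

    def fit(self, X, y) -> "YoudenThresholdClassifier":
        X, y = check_X_y(X, y, ensure_2d=True)
        if X.shape[1] != 1:
            raise ValueError("this classifier uses exactly one feature")
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes")
        y01 = (y == self.classes_[1]).astype(int)
        self.roc_ = roc_analysis(X[:, 0], y01, direction=self.direction)
        self.cutoff_ = self.roc_.cutoff
        self.auc_ = self.roc_.auc
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        X = check_array(X, ensure_2d=True)
        pred01 = self.roc_.predict(X[:, 0])
        return self.classes_[pred01]

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        X = check_array(X, ensure_2d=True)
        sign = 1.0 if self.direction == "greater" else -1.0
        return sign * (X[:, 0] - self.cutoff_)
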