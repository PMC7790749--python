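"""Clinically thresholded evaluation of pathogenicity probabilities.

Variants are called three ways at a pair of probability thresholds chosen to
mirror the >=90% confidence level expected for likely-pathogenic /
likely-benign assertions under ACMG/AMP-style interpretation:

* disease-causing when Pr >= upper (default 0.9),
* benign when Pr <= lower (default 0.1),
* indeterminate in between.

From these calls a single :class:`ClinicalMetricSuite` collects the confusion
counts and the derived rates. Denominators for TPR/TNR include indeterminate
calls, so TPR + FNR <= 1 and the remainder is the indeterminate fraction — the
quantity the three-way scheme is designed to expose. The suite satisfies two
exact identities on every input:

    overall_accuracy = proportion_high_confidence * accuracy_high_confidence
    proportion_indeterminate = 1 - proportion_high_confidence

Rates with a zero denominator are NaN and listed in ``undefined``; they are
never silently reported as 0.

The module also provides threshold-free curve metrics (ROC-AUC as the
Mann-Whitney probability, PR-AUC in average-precision form, Brier score),
paired permutation and DeLong tests for comparing two classifiers on the same
variants, and prevalence-adjusted predictive values for projecting holdout
TPR/TNR onto populations with a different proportion of pathogenic variants.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DomainError, UsageError

logger = logging.getLogger(__name__)

CALL_DISEASE_CAUSING = "disease-causing"
CALL_INDETERMINATE = "indeterminate"
CALL_BENIGN = "benign"

#: Problem sizes up to which paired permutation tests enumerate all 2^n swaps.
EXHAUSTIVE_SWAP_LIMIT = 12
#: Number of group-mask arrangements up to which subgroup tests enumerate.
EXHAUSTIVE_SHUFFLE_LIMIT = 20000


@dataclass(frozen=True)
class ThresholdPair:
    """Upper/lower probability thresholds for the three-way clinical call."""

    upper: float = 0.9
    lower: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise DomainError(
                f"require 0 < lower < upper < 1, got lower={self.lower} upper={self.upper}"
            )


def classify_three_way(pr: float, t: ThresholdPair = ThresholdPair()) -> str:
    """Three-way clinical call; boundaries are inclusive toward confident calls."""
    if not (0.0 <= pr <= 1.0):
        raise DomainError(f"probability {pr} outside [0, 1]")
    if pr >= t.upper:
        return CALL_DISEASE_CAUSING
    if pr <= t.lower:
        return CALL_BENIGN
    return CALL_INDETERMINATE


@dataclass
class ClinicalMetricSuite:
    """All thresholded performance quantities for one (labels, Pr) set."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    indeterminate_pathogenic: int
    indeterminate_benign: int
    tpr: float
    tnr: float
    ppv: float
    npv: float
    overall_accuracy: float
    proportion_high_confidence: float
    accuracy_high_confidence: float
    proportion_indeterminate: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def confusion_summary(
    labels: Sequence[int],
    prs: Sequence[float],
    t: ThresholdPair = ThresholdPair(),
) -> ClinicalMetricSuite:
    """Thresholded confusion counts and derived rates.

    ``labels``: 1 = pathogenic, 0 = benign. TPR/TNR denominators are the full
    class sizes (indeterminate calls count against sensitivity/specificity);
    PPV/NPV condition on the high-confidence call.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(prs, dtype=float)
    if y.shape != p.shape:
        raise UsageError(f"labels ({y.shape}) and probabilities ({p.shape}) misaligned")
    if y.size == 0:
        raise UsageError("need at least one variant")
    calls = np.array([classify_three_way(float(x), t) for x in p])

    tp = int(((y == 1) & (calls == CALL_DISEASE_CAUSING)).sum())
    fn = int(((y == 1) & (calls == CALL_BENIGN)).sum())
    ind_p = int(((y == 1) & (calls == CALL_INDETERMINATE)).sum())
    tn = int(((y == 0) & (calls == CALL_BENIGN)).sum())
    fp = int(((y == 0) & (calls == CALL_DISEASE_CAUSING)).sum())
    ind_b = int(((y == 0) & (calls == CALL_INDETERMINATE)).sum())

    n = y.size
    n_path = tp + fn + ind_p
    n_ben = tn + fp + ind_b
    n_hc = tp + fp + tn + fn
    undefined: list[str] = []
    return ClinicalMetricSuite(
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        indeterminate_pathogenic=ind_p,
        indeterminate_benign=ind_b,
        tpr=_safe_div(tp, n_path, "tpr", undefined),
        tnr=_safe_div(tn, n_ben, "tnr", undefined),
        ppv=_safe_div(tp, tp + fp, "ppv", undefined),
        npv=_safe_div(tn, tn + fn, "npv", undefined),
        overall_accuracy=(tp + tn) / n,
        proportion_high_confidence=n_hc / n,
        accuracy_high_confidence=_safe_div(tp + tn, n_hc, "accuracy_high_confidence", undefined),
        proportion_indeterminate=(ind_p + ind_b) / n,
        undefined=undefined,
    )


def percent(x: float, decimals: int = 1) -> float:
    """Reporting-layer formatting: fraction -> percentage, half-up rounding."""
    if math.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Curve metrics
# ---------------------------------------------------------------------------

def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC: P(score_pathogenic > score_benign) + 1/2 P(tie).

    NaN when one class is absent.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, s))


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """PR-AUC in average-precision (step) form: sum_k (R_k - R_{k-1}) P_k.

    Descending unique score thresholds, ties processed as one block; no
    trapezoidal interpolation. NaN when no pathogenic rows are present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if (y == 1).sum() == 0:
        return float("nan")
    return float(average_precision_score(y, s))


def brier(labels: Sequence[int], prs: Sequence[float]) -> float:
    """Mean squared difference between Pr and the 0/1 label (lower = better)."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(prs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("probabilities outside [0, 1]")
    return float(np.mean((p - y) ** 2))


def overall_accuracy_metric(labels: Sequence[int], prs: Sequence[float]) -> float:
    """Thresholded overall accuracy at the default 0.9/0.1 thresholds."""
    return confusion_summary(labels, prs).overall_accuracy


METRICS: dict[str, Callable[[Sequence[int], Sequence[float]], float]] = {
    "roc_auc": roc_auc,
    "pr_auc": pr_auc,
    "brier": brier,
    "overall_accuracy": overall_accuracy_metric,
}


def get_metric(name: str) -> Callable[[Sequence[int], Sequence[float]], float]:
    try:
        return METRICS[name]
    except KeyError:
        raise UsageError(f"unknown metric '{name}'; known: {sorted(METRICS)}") from None


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def paired_permutation_test(
    metric: str,
    labels: Sequence[int],
    prs_a: Sequence[float],
    prs_b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided p for a paired metric difference between two classifiers.

    The null swaps the two classifiers' scores independently per variant.
    Exhaustive over all 2^n swap patterns when n <= 12; otherwise Monte Carlo
    with the add-one correction p = (b + 1) / (n_perm + 1).
    """
    f = get_metric(metric)
    y = np.asarray(labels, dtype=int)
    a = np.asarray(prs_a, dtype=float)
    b = np.asarray(prs_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise UsageError("labels and both score vectors must be aligned")
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    n = y.size
    obs = abs(f(y, a) - f(y, b))
    tol = 1e-12  # float-noise guard on the >= comparison

    if n <= EXHAUSTIVE_SWAP_LIMIT:
        count = 0
        total = 2**n
        for bits in itertools.product((False, True), repeat=n):
            mask = np.array(bits)
            pa = np.where(mask, b, a)
            pb = np.where(mask, a, b)
            if abs(f(y, pa) - f(y, pb)) >= obs - tol:
                count += 1
        return count / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        mask = rng.random(n) < 0.5
        pa = np.where(mask, b, a)
        pb = np.where(mask, a, b)
        if abs(f(y, pa) - f(y, pb)) >= obs - tol:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    comp = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return comp.mean(axis=1), (1.0 - comp).mean(axis=0)


def delong_test(
    labels: Sequence[int],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
) -> tuple[float, float]:
    """Paired DeLong test for the difference of two correlated ROC-AUCs.

    Returns ``(auc_a - auc_b, two-sided p)`` using the placement-value
    covariance estimator and a normal reference for z = dAUC / sqrt(var).
    Degenerate var = 0: p = 1 if the difference is 0, else p = 0 (warned).
    """
    y = np.asarray(labels, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise UsageError("labels and both score vectors must be aligned")
    if len(np.unique(y)) < 2:
        raise UsageError("both classes must be present")
    pos, neg = y == 1, y == 0
    v10 = np.empty((2, pos.sum()))
    v01 = np.empty((2, neg.sum()))
    for i, s in enumerate((a, b)):
        v10[i], v01[i] = _placements(s[pos], s[neg])
    aucs = v10.mean(axis=1)
    d = float(aucs[0] - aucs[1])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ s10 @ contrast) / pos.sum() + float(
        contrast @ s01 @ contrast
    ) / neg.sum()
    if var <= 0:
        if d == 0.0:
            return d, 1.0
        logger.warning("DeLong variance is 0 with nonzero AUC difference; p set to 0")
        return d, 0.0
    z = d / math.sqrt(var)
    return d, float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Prevalence projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictiveValueRates:
    """High-confidence call rates from a holdout set, used for projection.

    ``fnr`` is the fraction of pathogenic variants confidently called benign
    and ``fpr`` the fraction of benign variants confidently called
    disease-causing; the remainders up to 1 are indeterminate calls.
    """

    tpr: float
    fnr: float
    tnr: float
    fpr: float

    def __post_init__(self) -> None:
        for name in ("tpr", "fnr", "tnr", "fpr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")
        if self.tpr + self.fnr > 1.0 + 1e-12:
            raise DomainError("tpr + fnr must be <= 1")
        if self.tnr + self.fpr > 1.0 + 1e-12:
            raise DomainError("tnr + fpr must be <= 1")

    @classmethod
    def from_suite(cls, s: ClinicalMetricSuite) -> "PredictiveValueRates":
        n_path = s.tp + s.fn + s.indeterminate_pathogenic
        n_ben = s.tn + s.fp + s.indeterminate_benign
        if n_path == 0 or n_ben == 0:
            raise DomainError("both classes required to derive predictive-value rates")
        return cls(tpr=s.tp / n_path, fnr=s.fn / n_path, tnr=s.tn / n_ben, fpr=s.fp / n_ben)


def predictive_values_at_prevalence(
    r: PredictiveValueRates, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV of the high-confidence calls at a given prevalence.

    Bayes projection of holdout TPR/FPR (and TNR/FNR) onto a population where
    a fraction ``prevalence`` of tested variants is truly pathogenic:

        PPV = pi*TPR / (pi*TPR + (1-pi)*FPR)
        NPV = (1-pi)*TNR / ((1-pi)*TNR + pi*FNR)

    NaN where a denominator is 0 (no confident calls of that kind are made).
    """
    if not (0.0 < prevalence < 1.0):
        raise DomainError(f"prevalence must be in (0, 1), got {prevalence}")
    pi = prevalence
    ppv_den = pi * r.tpr + (1 - pi) * r.fpr
    npv_den = (1 - pi) * r.tnr + pi * r.fnr
    ppv = pi * r.tpr / ppv_den if ppv_den > 0 else float("nan")
    npv = (1 - pi) * r.tnr / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


# ---------------------------------------------------------------------------
# Subgroup evaluation
# ---------------------------------------------------------------------------

def evaluate_subgroups(
    labels: Sequence[int],
    prs: Sequence[float],
    mask: Sequence[bool],
    t: ThresholdPair = ThresholdPair(),
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[ClinicalMetricSuite, ClinicalMetricSuite, float]:
    """Metric suites for two index-defined subsets and a permutation p-value.

    ``mask`` splits the variants into group True and group False (e.g. seen
    vs. unseen by some resource). The p-value is two-sided for the difference
    of overall accuracies under random shuffles of the group assignment;
    exhaustive over arrangements when their number is small, otherwise Monte
    Carlo with the add-one correction.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(prs, dtype=float)
    g = np.asarray(mask, dtype=bool)
    if not (y.shape == p.shape == g.shape):
        raise UsageError("labels, probabilities and mask must be aligned")
    n1 = int(g.sum())
    if n1 == 0 or n1 == g.size:
        raise UsageError("both groups must be non-empty")

    def acc_diff(mask_: np.ndarray) -> float:
        a1 = confusion_summary(y[mask_], p[mask_], t).overall_accuracy
        a0 = confusion_summary(y[~mask_], p[~mask_], t).overall_accuracy
        return a1 - a0

    suite_true = confusion_summary(y[g], p[g], t)
    suite_false = confusion_summary(y[~g], p[~g], t)
    obs = abs(acc_diff(g))
    tol = 1e-12

    n = g.size
    if math.comb(n, n1) <= EXHAUSTIVE_SHUFFLE_LIMIT:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            total += 1
            if abs(acc_diff(m)) >= obs - tol:
                count += 1
        pval = count / total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=n1, replace=False)] = True
            if abs(acc_diff(m)) >= obs - tol:
                hits += 1
        pval = (hits + 1) / (n_perm + 1)
    return suite_true, suite_false, pval
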