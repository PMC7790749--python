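"""Cohort-level validation of a variant classifier, independent of labels.

Two lines of evidence that a pathogenicity classifier is ranking the right
variants, neither of which uses the gold-standard labels:

1. **Case-control enrichment.** For each disease gene, carriers of rare
   missense variants are counted in a patient cohort and a population
   reference cohort (one carrier per gene per cohort). If the classifier
   works, the odds ratio for carriers of *predicted disease-causing* variants
   should exceed the all-rare-variant baseline, and the predicted-benign
   stratum should fall below it. Odds ratios use the cross-product ratio with
   the Haldane-Anscombe +0.5 correction on zero cells and Woolf (log-scale)
   confidence intervals; strata are compared to the baseline with a z-test on
   the difference of log odds ratios (conservative: the strata share
   controls, so the independence variance overstates the true one).

2. **Outcome stratification.** Patients grouped by their predicted genotype
   class (predicted disease-causing carrier / predicted benign carrier /
   genotype-negative) are compared on age-to-first-composite-event records:
   Kaplan-Meier event-free survival, pairwise log-rank tests, Cox
   proportional-hazards ratios (Breslow tie handling), and the difference of
   cumulative event incidence at a landmark age with a percentile bootstrap
   confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.stats import norm
from statsmodels.duration.hazard_regression import PHReg

from .errors import DomainError, UsageError

logger = logging.getLogger(__name__)

STRATUM_ALL = "all-rare"
STRATUM_DISEASE_CAUSING = "predicted-disease-causing"
STRATUM_BENIGN = "predicted-benign"


@dataclass(frozen=True)
class GeneCountTable:
    """2x2 carrier table for one gene and one variant stratum.

    ``a``/``b``: carriers / non-carriers in the case cohort;
    ``c``/``d``: carriers / non-carriers in the reference cohort.
    """

    gene: str
    stratum: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError(f"{self.gene}/{self.stratum}: counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DomainError(f"{self.gene}/{self.stratum}: cohort sizes must be > 0")


@dataclass(frozen=True)
class ORResult:
    """Odds-ratio point estimate with Woolf 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied
    log_or: float
    se_log_or: float


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: age at first composite event or censoring, and stratum."""

    patient_id: str
    age: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise DomainError(f"{self.patient_id}: age must be finite and positive")


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

def gene_odds_ratio(tab: GeneCountTable) -> ORResult:
    """Cross-product odds ratio (a*d)/(b*c) with Woolf CI.

    When any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe)
    and the result is flagged as corrected.
    """
    cells = np.array([tab.a, tab.b, tab.c, tab.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        corrected=corrected,
        log_or=log_or,
        se_log_or=se,
    )


@dataclass(frozen=True)
class StratumComparison:
    """One stratum's OR and its z-test against the all-rare baseline."""

    stratum: str
    result: ORResult
    log_or_difference: Optional[float]  # None for the baseline row
    p_value: Optional[float]


def stratified_or_comparison(
    tables: Sequence[GeneCountTable],
) -> dict[str, StratumComparison]:
    """Per-stratum ORs for one gene and z-tests of each stratum vs. baseline.

    The variance of the log-OR difference is the sum of the two Woolf
    variances (independence approximation; conservative because the strata
    share the reference cohort).
    """
    genes = {t.gene for t in tables}
    if len(genes) != 1:
        raise UsageError(f"tables must concern a single gene, got {sorted(genes)}")
    by_stratum = {t.stratum: t for t in tables}
    if STRATUM_ALL not in by_stratum:
        raise UsageError(f"missing '{STRATUM_ALL}' baseline stratum")
    sizes = {(t.a + t.b, t.c + t.d) for t in tables}
    if len(sizes) != 1:
        raise UsageError("all strata must share the case and reference cohort sizes")

    base = gene_odds_ratio(by_stratum[STRATUM_ALL])
    out: dict[str, StratumComparison] = {
        STRATUM_ALL: StratumComparison(STRATUM_ALL, base, None, None)
    }
    for stratum, tab in by_stratum.items():
        if stratum == STRATUM_ALL:
            continue
        res = gene_odds_ratio(tab)
        diff = res.log_or - base.log_or
        se = math.sqrt(res.se_log_or**2 + base.se_log_or**2)
        p = float(2.0 * norm.sf(abs(diff) / se)) if se > 0 else (1.0 if diff == 0 else 0.0)
        out[stratum] = StratumComparison(stratum, res, diff, p)
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve over distinct event ages."""

    ages: np.ndarray  # distinct event ages, increasing
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(age) just after each event age

    def survival_at(self, age: float) -> float:
        """Step-function value S(age); 1 before the first event."""
        i = np.searchsorted(self.ages, age, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def cumulative_incidence_at(self, age: float) -> float:
        return 1.0 - self.survival_at(age)


def km_estimate(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier estimate of event-free survival from patient records."""
    if not records:
        raise UsageError("need at least one record")
    ages = np.array([r.age for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=events)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    event_ages = observed.index.to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_.loc[a].iloc[0]) for a in observed.index]
    )
    return SurvivalCurve(
        ages=event_ages,
        at_risk=observed["at_risk"].to_numpy(dtype=float),
        events=observed["observed"].to_numpy(dtype=float),
        survival=surv,
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    defined: bool


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test (1 df chi-square); undefined with no events."""
    if not group_a or not group_b:
        raise UsageError("both groups must be non-empty")
    if not any(r.event for r in (*group_a, *group_b)):
        return LogrankResult(float("nan"), float("nan"), defined=False)
    res = _lifelines_logrank(
        np.array([r.age for r in group_a]),
        np.array([r.age for r in group_b]),
        event_observed_A=np.array([r.event for r in group_a], dtype=bool),
        event_observed_B=np.array([r.event for r in group_b], dtype=bool),
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value), defined=True)


@dataclass(frozen=True)
class GroupHazard:
    """Hazard ratio of one group vs. the reference, with Wald CI and p."""

    group: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool


def cox_hr(
    records: Sequence[SurvivalRecord], reference_group: str
) -> dict[str, GroupHazard]:
    """Cox proportional-hazards model with group indicator covariates.

    Partial likelihood with Breslow tie handling; each non-reference group
    gets a Wald CI and p-value vs. ``reference_group``. A group with no
    events produces a monotone likelihood; its result is returned flagged as
    non-converged instead of raising.
    """
    groups = sorted({r.group for r in records})
    if reference_group not in groups:
        raise UsageError(f"reference group '{reference_group}' not present in records")
    if len(groups) < 2:
        raise UsageError("need at least two groups")
    if not any(r.event for r in records):
        raise UsageError("no events in the data; hazard ratios are undefined")

    others = [g for g in groups if g != reference_group]
    events_per_group = {g: sum(r.event for r in records if r.group == g) for g in groups}
    degenerate = {g for g in others if events_per_group[g] == 0}
    if events_per_group[reference_group] == 0:
        degenerate.update(others)  # no reference events: every contrast is monotone

    out: dict[str, GroupHazard] = {}
    fit_groups = [g for g in others if g not in degenerate]
    if fit_groups:
        keep = [r for r in records if r.group == reference_group or r.group in fit_groups]
        endog = np.array([r.age for r in keep])
        status = np.array([r.event for r in keep], dtype=float)
        exog = np.column_stack(
            [[1.0 if r.group == g else 0.0 for r in keep] for g in fit_groups]
        )
        model = PHReg(endog, exog, status=status, ties="breslow")
        try:
            fit = model.fit(disp=False)
            params = np.atleast_1d(fit.params)
            bse = np.atleast_1d(fit.bse)
            ok = np.isfinite(params) & np.isfinite(bse) & (bse > 0)
            for i, g in enumerate(fit_groups):
                if not ok[i]:
                    degenerate.add(g)
                    continue
                z = params[i] / bse[i]
                out[g] = GroupHazard(
                    group=g,
                    hazard_ratio=float(np.exp(params[i])),
                    ci_low=float(np.exp(params[i] - 1.96 * bse[i])),
                    ci_high=float(np.exp(params[i] + 1.96 * bse[i])),
                    p_value=float(2.0 * norm.sf(abs(z))),
                    converged=True,
                )
        except Exception as e:  # monotone likelihood and friends
            logger.warning("Cox fit failed (%s); flagging all contrasts", e)
            degenerate.update(fit_groups)

    for g in degenerate:
        out[g] = GroupHazard(g, float("nan"), float("nan"), float("nan"), float("nan"), False)
    return out


@dataclass(frozen=True)
class RiskDifference:
    """Cumulative-incidence difference at a landmark age, with bootstrap CI."""

    age: float
    risk_a: float
    risk_b: float
    difference: float
    ci_low: float
    ci_high: float
    defined: bool


def outcome_risk_by_age(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    age: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> RiskDifference:
    """Difference of cumulative incidence at ``age`` (group A minus group B).

    The CI is a percentile bootstrap over patients resampled within each
    group; seeded and deterministic. Flagged undefined when ``age`` exceeds
    the follow-up of either group.
    """
    if not group_a or not group_b:
        raise UsageError("both groups must be non-empty")
    max_a = max(r.age for r in group_a)
    max_b = max(r.age for r in group_b)
    if age > max_a or age > max_b:
        return RiskDifference(age, float("nan"), float("nan"), float("nan"),
                              float("nan"), float("nan"), defined=False)

    risk_a = km_estimate(group_a).cumulative_incidence_at(age)
    risk_b = km_estimate(group_b).cumulative_incidence_at(age)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    ga, gb = list(group_a), list(group_b)
    for i in range(n_boot):
        ra = [ga[j] for j in rng.integers(0, len(ga), len(ga))]
        rb = [gb[j] for j in rng.integers(0, len(gb), len(gb))]
        diffs[i] = km_estimate(ra).cumulative_incidence_at(age) - km_estimate(
            rb
        ).cumulative_incidence_at(age)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return RiskDifference(
        age=age,
        risk_a=risk_a,
        risk_b=risk_b,
        difference=risk_a - risk_b,
        ci_low=float(lo),
        ci_high=float(hi),
        defined=True,
    )


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def read_gene_counts(path) -> list[GeneCountTable]:
    """Read the cohort-counts TSV: gene, stratum, a, b, c, d."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "stratum", "a", "b", "c", "d"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise UsageError(f"cohort counts table missing column(s): {missing}")
    return [
        GeneCountTable(str(r.gene), str(r.stratum), int(r.a), int(r.b), int(r.c), int(r.d))
        for r in df.itertuples(index=False)
    ]


def read_survival_table(path) -> list[SurvivalRecord]:
    """Read the survival TSV: patient_id, age, event (0/1), group."""
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "age", "event", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise UsageError(f"survival table missing column(s): {missing}")
    return [
        SurvivalRecord(str(r.patient_id), float(r.age), bool(int(r.event)), str(r.group))
        for r in df.itertuples(index=False)
    ]
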