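"""Seeded generators for all three input kinds, with known ground truth.

Every generator is a pure function of its spec plus seed, so training,
evaluation and cohort analyses are fully testable without any download:

* :func:`gen_feature_table` — labeled variant feature tables with a
  controllable class separation ``d``: bounded [0, 1] scores are Beta-
  distributed with class means separated by ``d`` on the logit scale, and
  continuous annotations are Gaussians whose pathogenic mean is shifted by
  ``d``. ``d = 0`` gives an exact null; large ``d`` gives near-perfect
  separability.
* :func:`gen_cohort_counts` — per-gene case/reference carrier counts with a
  specified true odds ratio per gene.
* :func:`gen_survival_cohort` — exponential event ages with group-scaled
  hazards (specified true hazard ratios) under independent uniform censoring.

Defaults mirror the curation conditions of the cardiomyopathy training data:
356 pathogenic + 302 benign unique rare missense variants, 76 annotation
features across 16 disease genes, and 45% of variants absent from the
population reference (MAF missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_eval import GeneCountTable, SurvivalRecord, STRATUM_ALL
from .errors import DomainError
from .variant_data import FeatureKind, LabeledDataset, Variant, default_schema

#: Sarcomere / cardiomyopathy-associated gene symbols used for realism; the
#: generator cycles through them (then GENE17, GENE18, ... if more are asked).
_GENE_POOL = (
    "MYH7", "MYBPC3", "TNNT2", "TNNI3", "TPM1", "ACTC1", "MYL2", "MYL3",
    "CSRP3", "PLN", "FHL1", "VCL", "ACTN2", "TTN", "LMNA", "DES",
)

_BASES = ("A", "C", "G", "T")


def _gene_names(n_genes: int) -> list[str]:
    names = list(_GENE_POOL[:n_genes])
    names += [f"GENE{i + 1}" for i in range(len(names), n_genes)]
    return names


@dataclass(frozen=True)
class FeatureGenSpec:
    """Conditions for a synthetic labeled variant feature table."""

    n_pathogenic: int = 356
    n_benign: int = 302
    n_features: int = 76
    separation: float = 0.25  # per-feature effect size d
    unit_fraction: float = 0.5  # fraction of features that are [0,1] scores
    missing_rate: float = 0.05
    n_genes: int = 16
    maf_absent_prob: float = 0.45  # P(variant unseen in the reference)
    maf_cutoff: float = 0.001  # all generated MAFs fall strictly below
    beta_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unit_fraction", "missing_rate", "maf_absent_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")
        if self.separation < 0:
            raise DomainError("separation must be >= 0")
        if min(self.n_pathogenic, self.n_benign) < 1 or self.n_features < 1:
            raise DomainError("class sizes and n_features must be >= 1")
        if self.n_genes < 1:
            raise DomainError("n_genes must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_feature_table(spec: FeatureGenSpec) -> LabeledDataset:
    """Generate a labeled dataset that passes table validation unchanged."""
    rng = np.random.default_rng(spec.seed)
    schema = default_schema(spec.n_features, spec.unit_fraction)
    n = spec.n_pathogenic + spec.n_benign
    labels = rng.permutation(
        np.r_[np.ones(spec.n_pathogenic, int), np.zeros(spec.n_benign, int)]
    )

    d = spec.separation
    X = np.empty((n, spec.n_features))
    base_logit = rng.normal(0.0, 1.0, spec.n_features)  # per-feature baseline
    for j, kind in enumerate(schema.kinds):
        shift = np.where(labels == 1, d / 2.0, -d / 2.0)
        if kind is FeatureKind.UNIT_SCORE:
            mean = _sigmoid(base_logit[j] + shift)
            kappa = spec.beta_concentration
            X[:, j] = rng.beta(mean * kappa, (1.0 - mean) * kappa)
        else:
            X[:, j] = rng.normal(base_logit[j] + shift, 1.0)

    if spec.missing_rate > 0:
        X[rng.random(X.shape) < spec.missing_rate] = np.nan

    genes = _gene_names(spec.n_genes)
    maf_absent = rng.random(n) < spec.maf_absent_prob
    # log-uniform below the rarity cutoff, floor 1e-6
    maf = np.exp(rng.uniform(math.log(1e-6), math.log(spec.maf_cutoff), n))
    maf = np.minimum(maf, spec.maf_cutoff * (1 - 1e-9))
    variants = []
    for i in range(n):
        gene = genes[i % spec.n_genes]
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        variants.append(
            Variant(
                variant_id=f"chr{i % 22 + 1}-{1000 + i}-{ref}-{alt}",
                gene=gene,
                chrom=f"chr{i % 22 + 1}",
                pos=1000 + i,
                ref=ref,
                alt=alt,
                maf=None if maf_absent[i] else float(maf[i]),
            )
        )
    return LabeledDataset(variants=variants, features=X, schema=schema, labels=labels)


@dataclass(frozen=True)
class CohortGenSpec:
    """Conditions for synthetic per-gene case/reference carrier counts.

    ``genes`` maps gene symbol -> (true odds ratio, reference carrier
    frequency). Case carrier frequency is derived so the population odds
    ratio equals the requested one.
    """

    genes: dict = field(default_factory=lambda: {"MYH7": (5.0, 0.01)})
    n_cases: int = 5000
    n_controls: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, (or_, f) in self.genes.items():
            if or_ <= 0:
                raise DomainError(f"{gene}: odds ratio must be > 0")
            if not (0.0 < f < 1.0):
                raise DomainError(f"{gene}: carrier frequency must be in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise DomainError("cohort sizes must be >= 1")


def case_frequency(odds_ratio: float, control_frequency: float) -> float:
    """Carrier frequency in cases implied by a true OR and control frequency."""
    odds = odds_ratio * control_frequency / (1.0 - control_frequency)
    f = odds / (1.0 + odds)
    if not (0.0 < f < 1.0):
        raise DomainError(f"implied case frequency {f} outside (0, 1)")
    return f


def gen_cohort_counts(spec: CohortGenSpec) -> list[GeneCountTable]:
    """Binomial carrier counts per gene at the specified true odds ratios."""
    rng = np.random.default_rng(spec.seed)
    tables = []
    for gene, (or_, f) in spec.genes.items():
        f_case = case_frequency(or_, f)
        a = int(rng.binomial(spec.n_cases, f_case))
        c = int(rng.binomial(spec.n_controls, f))
        tables.append(
            GeneCountTable(
                gene=gene,
                stratum=STRATUM_ALL,
                a=a,
                b=spec.n_cases - a,
                c=c,
                d=spec.n_controls - c,
            )
        )
    return tables


@dataclass(frozen=True)
class SurvivalGenSpec:
    """Conditions for a synthetic survival cohort.

    ``groups`` maps group name -> (n patients, true hazard ratio vs. the
    baseline rate). Event ages are exponential with hazard
    ``baseline_rate * HR``; censoring ages are Uniform(censor_low,
    censor_high), drawn independently.
    """

    groups: dict = field(
        default_factory=lambda: {
            "genotype-negative": (1927, 1.0),
            "predicted-disease-causing": (803, 1.9),
        }
    )
    baseline_rate: float = 1.0 / 80.0  # events per year; ~median onset 55y
    censor_low: float = 20.0
    censor_high: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise DomainError("baseline_rate must be > 0")
        for g, (n, hr) in self.groups.items():
            if n < 1:
                raise DomainError(f"{g}: group size must be >= 1")
            if hr <= 0:
                raise DomainError(f"{g}: hazard ratio must be > 0")
        if not (0.0 <= self.censor_low < self.censor_high):
            raise DomainError("require 0 <= censor_low < censor_high")


def gen_survival_cohort(spec: SurvivalGenSpec) -> list[SurvivalRecord]:
    """Exponential event ages with group-scaled hazards, uniform censoring."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for group, (n, hr) in spec.groups.items():
        event_age = rng.exponential(1.0 / (spec.baseline_rate * hr), n)
        censor_age = rng.uniform(spec.censor_low, spec.censor_high, n)
        age = np.minimum(event_age, censor_age)
        age = np.maximum(age, 1e-9)  # ages must be strictly positive
        event = event_age <= censor_age
        for i in range(n):
            records.append(
                SurvivalRecord(
                    patient_id=f"{group}-{i}",
                    age=float(age[i]),
                    event=bool(event[i]),
                    group=group,
                )
            )
    return records
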