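"""Reading, validation, curation and splitting of labeled variant feature tables.

The unit of analysis is the unique rare missense variant: one row per variant,
identified as ``chrom-pos-ref-alt``, carrying a gene symbol, a population minor
allele frequency (MAF, absent when the variant is unseen in the reference
population), a binary clinical label (pathogenic / benign) and a fixed-width
vector of functional-annotation features described by a :class:`FeatureSchema`.

Curation follows the conventions of clinical variant classification:

* rarity is a strict MAF cutoff (default 0.1%); variants absent from the
  reference population are treated as rare, since a substantial fraction of
  disease-associated variants are never observed in population controls;
* labels are derived from multisets of clinical assertions (P/LP/B/LB/VUS);
  any conflict between assertion classes, or any VUS, excludes the variant;
* train/test splitting is stratified by class and deterministic under a seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DomainError,
    SchemaError,
    StratificationError,
    UsageError,
    ValidationError,
)

#: Columns every feature table must provide before the schema features.
MANDATORY_COLUMNS = ("variant_id", "gene", "chrom", "pos", "ref", "alt", "label", "maf")

#: Recognized clinical label vocabulary for the ``label`` column.
LABEL_VOCABULARY = ("pathogenic", "benign")

#: Recognized clinical assertion tokens.
ASSERTION_TOKENS = frozenset({"P", "LP", "B", "LB", "VUS"})

_PATHOGENIC_ASSERTIONS = frozenset({"P", "LP"})
_BENIGN_ASSERTIONS = frozenset({"B", "LB"})


class FeatureKind(str, enum.Enum):
    """Statistical kind of a feature column."""

    UNIT_SCORE = "unit_score"  # bounded score in [0, 1]
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"  # numerically coded categories


@dataclass(frozen=True)
class Variant:
    """Identity and population frequency of one missense variant."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"{self.variant_id}: ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"{self.variant_id}: ref equals alt ({self.ref})")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValidationError(f"{self.variant_id}: maf {self.maf} outside [0, 1]")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, persisted description of the feature columns.

    The order of ``names`` is fixed: it defines the column order of every
    feature matrix and is stored with any fitted model.
    """

    names: tuple[str, ...]
    kinds: tuple[FeatureKind, ...]
    missing_allowed: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        if not (len(self.names) == len(self.kinds) == len(self.missing_allowed)):
            raise SchemaError("names, kinds and missing_allowed must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "kinds": [k.value for k in self.kinds],
            "missing_allowed": list(self.missing_allowed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            names=tuple(d["names"]),
            kinds=tuple(FeatureKind(k) for k in d["kinds"]),
            missing_allowed=tuple(bool(m) for m in d["missing_allowed"]),
        )


def default_schema(n_features: int = 76, unit_fraction: float = 0.5) -> FeatureSchema:
    """Placeholder annotation schema of ``n_features`` columns.

    Stands in for a full functional-annotation panel (conservation scores,
    in-silico predictor outputs, protein-level annotations...): the first
    ``round(n_features * unit_fraction)`` columns are bounded [0, 1] scores
    named ``score_i``, the rest unbounded continuous annotations named
    ``anno_i``. All columns allow missing values, as real annotation tables do.
    """
    n_unit = int(round(n_features * unit_fraction))
    names = tuple(f"score_{i}" for i in range(n_unit)) + tuple(
        f"anno_{i}" for i in range(n_features - n_unit)
    )
    kinds = (FeatureKind.UNIT_SCORE,) * n_unit + (FeatureKind.CONTINUOUS,) * (
        n_features - n_unit
    )
    return FeatureSchema(names=names, kinds=kinds, missing_allowed=(True,) * n_features)


@dataclass
class LabeledDataset:
    """Variants + feature matrix (+ optional binary labels).

    ``features`` is an ``(n, p)`` float array conforming to ``schema``; missing
    entries are NaN. ``labels`` is an int array with pathogenic = 1 and
    benign = 0, or ``None`` for unlabeled (prediction-only) inputs.
    """

    variants: list[Variant]
    features: np.ndarray
    schema: FeatureSchema
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape != (len(self.variants), len(self.schema)):
            raise ValidationError(
                f"feature matrix shape {self.features.shape} does not match "
                f"{len(self.variants)} variants x {len(self.schema)} features"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.variants),):
                raise ValidationError("labels length does not match variant count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be 0 (benign) or 1 (pathogenic)")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate variant_id values: {dupes}")
        for j, (name, kind) in enumerate(zip(self.schema.names, self.schema.kinds)):
            col = self.features[:, j]
            present = col[~np.isnan(col)]
            if kind is FeatureKind.UNIT_SCORE and present.size and (
                (present < 0).any() or (present > 1).any()
            ):
                raise ValidationError(f"unit_score feature '{name}' has values outside [0, 1]")
            if not self.schema.missing_allowed[j] and np.isnan(col).any():
                raise ValidationError(f"feature '{name}' does not allow missing values")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_pathogenic(self) -> int:
        if self.labels is None:
            raise UsageError("dataset is unlabeled")
        return int(self.labels.sum())

    @property
    def n_benign(self) -> int:
        if self.labels is None:
            raise UsageError("dataset is unlabeled")
        return int((self.labels == 0).sum())

    def subset(self, idx: Sequence[int] | np.ndarray) -> "LabeledDataset":
        """Row subset in the given order; features are copied."""
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            variants=[self.variants[i] for i in idx],
            features=self.features[idx].copy(),
            schema=self.schema,
            labels=None if self.labels is None else self.labels[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form (mandatory columns + schema features)."""
        rows = {
            "variant_id": [v.variant_id for v in self.variants],
            "gene": [v.gene for v in self.variants],
            "chrom": [v.chrom for v in self.variants],
            "pos": [v.pos for v in self.variants],
            "ref": [v.ref for v in self.variants],
            "alt": [v.alt for v in self.variants],
            "label": (
                [""] * len(self)
                if self.labels is None
                else ["pathogenic" if y else "benign" for y in self.labels]
            ),
            "maf": [v.maf if v.maf is not None else np.nan for v in self.variants],
        }
        df = pd.DataFrame(rows)
        for j, name in enumerate(self.schema.names):
            df[name] = self.features[:, j]
        return df


@dataclass(frozen=True)
class AssertionSet:
    """Multiset of clinical assertions (P/LP/B/LB/VUS) for one variant."""

    assertions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.assertions:
            raise ValidationError("assertion set must be non-empty")
        unknown = sorted(set(self.assertions) - ASSERTION_TOKENS)
        if unknown:
            raise ValidationError(f"unknown assertion tokens: {unknown}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_numeric(col: pd.Series) -> np.ndarray:
    """'NA', '' and unparseable cells become NaN; everything else float."""
    return pd.to_numeric(col.mask(col.isin(("NA", ""))), errors="coerce").to_numpy(dtype=float)


def read_feature_table(path: str | Path, schema: FeatureSchema) -> LabeledDataset:
    """Read a tab-separated labeled variant feature table.

    The file must have a header naming at least the mandatory columns
    (``variant_id gene chrom pos ref alt label maf``) and every feature of
    ``schema``; features are reordered into schema order. ``NA`` and empty
    cells are missing; the label column must be ``pathogenic`` or ``benign``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in (*MANDATORY_COLUMNS, *schema.names) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    dupes = df["variant_id"][df["variant_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate variant_id values: {sorted(dupes)}")

    bad = df.index[~df["label"].isin(LABEL_VOCABULARY)]
    if len(bad):
        row = int(bad[0]) + 2  # 1-based, counting the header line
        raise ValidationError(
            f"label '{df.loc[bad[0], 'label']}' at line {row} not in {list(LABEL_VOCABULARY)}"
        )

    maf = _parse_numeric(df["maf"])
    variants = [
        Variant(
            variant_id=r.variant_id,
            gene=r.gene,
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            maf=None if np.isnan(m) else float(m),
        )
        for r, m in zip(df.itertuples(index=False), maf)
    ]
    features = np.column_stack([_parse_numeric(df[name]) for name in schema.names])
    labels = (df["label"] == "pathogenic").to_numpy(dtype=int)
    return LabeledDataset(variants=variants, features=features, schema=schema, labels=labels)


def read_vcf(path: str | Path, schema: FeatureSchema, mapping: str | Path | dict) -> LabeledDataset:
    """Read variants from a VCF (v4.2), feature values from INFO keys.

    ``mapping`` is a YAML file (or dict) with a ``features`` block mapping
    schema feature names to INFO keys, optionally ``maf`` and ``label`` INFO
    keys. Multiallelic records are rejected. Returns an unlabeled dataset
    unless a ``label`` key is mapped (label INFO values must be
    ``pathogenic``/``benign``).
    """
    from cyvcf2 import VCF  # deferred: only VCF users pay the import

    if not isinstance(mapping, dict):
        with open(mapping) as fh:
            mapping = yaml.safe_load(fh)
    feat_map: dict = mapping.get("features", {})
    missing = [n for n in schema.names if n not in feat_map]
    if missing:
        raise SchemaError(f"VCF mapping missing feature key(s): {missing}")
    maf_key = mapping.get("maf")
    label_key = mapping.get("label")

    variants: list[Variant] = []
    rows: list[list[float]] = []
    labels: list[int] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} not supported; "
                "split into biallelic records first"
            )
        alt = rec.ALT[0]
        maf = rec.INFO.get(maf_key) if maf_key else None
        variants.append(
            Variant(
                variant_id=f"{rec.CHROM}-{rec.POS}-{rec.REF}-{alt}",
                gene=str(rec.INFO.get("GENE", "")),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                maf=None if maf is None else float(maf),
            )
        )
        row = []
        for name in schema.names:
            v = rec.INFO.get(feat_map[name])
            try:
                row.append(float(v))
            except (TypeError, ValueError):
                row.append(np.nan)
        rows.append(row)
        if label_key:
            lab = rec.INFO.get(label_key)
            if lab not in LABEL_VOCABULARY:
                raise ValidationError(
                    f"label INFO value {lab!r} at {rec.CHROM}:{rec.POS} "
                    f"not in {list(LABEL_VOCABULARY)}"
                )
            labels.append(1 if lab == "pathogenic" else 0)

    features = np.asarray(rows, dtype=float).reshape(len(variants), len(schema))
    return LabeledDataset(
        variants=variants,
        features=features,
        schema=schema,
        labels=np.asarray(labels, dtype=int) if label_key else None,
    )


def write_feature_table(ds: LabeledDataset, path: str | Path) -> None:
    """Write the canonical TSV form (missing values as empty cells)."""
    ds.to_frame().to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def filter_rare(ds: LabeledDataset, maf_cutoff: float = 0.001) -> LabeledDataset:
    """Keep variants with MAF strictly below ``maf_cutoff`` or MAF absent.

    Absent MAF (variant unseen in the reference population) counts as rare.
    Row order is preserved; idempotent; returns a new dataset.
    """
    if not (0.0 < maf_cutoff <= 1.0):
        raise DomainError(f"maf_cutoff must be in (0, 1], got {maf_cutoff}")
    keep = [i for i, v in enumerate(ds.variants) if v.maf is None or v.maf < maf_cutoff]
    return ds.subset(keep)


def curate_label(a: AssertionSet | Iterable[str]) -> str:
    """Collapse a multiset of clinical assertions into a training label.

    ``pathogenic`` iff every assertion is P or LP; ``benign`` iff every
    assertion is B or LB; anything else — any mixture of opposing classes or
    any VUS — is ``excluded`` (conflicting interpretation). Order-invariant.
    """
    if not isinstance(a, AssertionSet):
        a = AssertionSet(tuple(a))
    tokens = set(a.assertions)
    if tokens <= _PATHOGENIC_ASSERTIONS:
        return "pathogenic"
    if tokens <= _BENIGN_ASSERTIONS:
        return "benign"
    return "excluded"


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_test(
    ds: LabeledDataset, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split, deterministic under ``seed``.

    Per class, ``ceil(n_class * train_fraction)`` rows go to train (the
    fractional remainder is assigned to train), so each class's train share
    deviates from ``train_fraction`` by less than one variant. The two parts
    are disjoint and exhaustive.
    """
    if not (0.0 < train_fraction < 1.0):
        raise DomainError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if ds.labels is None:
        raise UsageError("split_train_test requires a labeled dataset")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(ds.labels == cls)
        if cls_idx.size < 2:
            raise StratificationError(
                f"class {cls} has {cls_idx.size} row(s); need >= 2 to stratify"
            )
        perm = rng.permutation(cls_idx)
        n_train = int(np.ceil(cls_idx.size * train_fraction - 1e-9))
        n_train = min(max(n_train, 1), cls_idx.size - 1)  # both parts non-empty
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    return ds.subset(train_idx), ds.subset(test_idx)
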