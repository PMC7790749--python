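import numpy as np
import pytest

from cardioclass import (
    FeatureGenSpec,
    FeatureKind,
    FeatureSchema,
    LabeledDataset,
    Variant,
    gen_feature_table,
)


def make_schema(names, kinds=None):
    kinds = kinds or [FeatureKind.CONTINUOUS] * len(names)
    return FeatureSchema(
        names=tuple(names), kinds=tuple(kinds), missing_allowed=(True,) * len(names)
    )


def make_dataset(X, y, schema=None):
    """LabeledDataset from a raw matrix with auto-generated variant identities."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    schema = schema or make_schema([f"f{j}" for j in range(X.shape[1])])
    variants = [
        Variant(f"chr1-{i + 1}-A-G", "MYH7", "chr1", i + 1, "A", "G", maf=None)
        for i in range(X.shape[0])
    ]
    return LabeledDataset(variants=variants, features=X, schema=schema, labels=np.asarray(y))


@pytest.fixture
def tiny_separable():
    """1-D dataset, pathogenic iff x > 0, with a wide separating gap."""
    X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    return make_dataset(X, y)


@pytest.fixture
def moderate_dataset():
    """Seeded synthetic table with moderate class overlap (fast fixture)."""
    return gen_feature_table(
        FeatureGenSpec(
            n_pathogenic=60, n_benign=60, n_features=8, separation=1.0, missing_rate=0.05, seed=11
        )
    )


@pytest.fixture
def feature_tsv(tmp_path, moderate_dataset):
    from cardioclass import write_feature_table

    path = tmp_path / "variants.tsv"
    write_feature_table(moderate_dataset, path)
    return path
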