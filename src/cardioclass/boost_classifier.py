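"""Discrete AdaBoost over depth-limited decision trees, with JSON serialization.

The classifier outputs a probability of pathogenicity Pr in [0, 1] per variant.
Boosting follows the classic discrete (exponential-loss) scheme: sample weights
start uniform; each round fits a depth-limited CART tree on the weighted data,
its weighted 0/1 error eps_m determines the round weight

    alpha_m = 1/2 * ln((1 - eps_m) / eps_m),

misclassified samples are up-weighted by exp(2 * alpha_m) and weights are
renormalized. A round with eps_m = 0 is kept with alpha capped at ln(10^6) and
boosting stops (nothing left to reweight); a round with eps_m >= 1/2 is no
better than chance, is discarded, and boosting stops.

The probability transform is the normalized weighted vote

    Pr = sum_m alpha_m * 1[tree_m votes pathogenic] / sum_m alpha_m,

a deliberate design choice: it is bounded, monotone in each tree's vote, and
exactly reproducible from the serialized model. It is *not* a calibrated
posterior; see docs/methods.md for the discussion.

Missing feature values are imputed with per-feature training medians that are
learned in :func:`fit_adaboost` and stored inside the model, so prediction
needs nothing beyond the model file.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import ModelLoadError, SchemaError, UsageError
from .variant_data import FeatureSchema, LabeledDataset

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Round weight assigned when a tree classifies the weighted sample perfectly.
ALPHA_CAP = math.log(1e6)


def _tree_to_nodes(tree: DecisionTreeClassifier) -> dict:
    """Serialize a fitted sklearn tree into nested split/leaf dicts.

    Leaves carry the majority vote (pathogenic = 1); ties go to the lower
    class index, matching ``tree.predict``.
    """
    t = tree.tree_
    classes = tree.classes_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            vote = int(classes[int(np.argmax(t.value[i]))])
            return {"vote": vote}
        return {
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(int(t.children_left[i])),
            "right": node(int(t.children_right[i])),
        }

    return node(0)


def _nodes_predict(node: dict, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation of a serialized tree on an imputed matrix."""
    out = np.empty(X.shape[0], dtype=int)

    def walk(nd: dict, idx: np.ndarray) -> None:
        if "vote" in nd:
            out[idx] = nd["vote"]
            return
        go_left = X[idx, nd["feature"]] <= nd["threshold"]
        walk(nd["left"], idx[go_left])
        walk(nd["right"], idx[~go_left])

    walk(node, np.arange(X.shape[0]))
    return out


@dataclass
class BoostRound:
    """One boosting round: a serialized tree, its weight and weighted error."""

    nodes: dict
    alpha: float
    epsilon: float


@dataclass
class BoostModel:
    """Fitted boosted-tree ensemble: the unit of prediction and serialization."""

    schema: FeatureSchema
    imputation: np.ndarray  # per-feature training medians
    rounds: list[BoostRound]
    n_rounds_requested: int
    tree_depth: int
    seed: int
    stopping_reason: str = "completed"

    def __post_init__(self) -> None:
        if not self.rounds:
            raise UsageError("a model must contain at least one round")
        alphas = np.array([r.alpha for r in self.rounds])
        if not np.isfinite(alphas).all() or (alphas < 0).any():
            raise UsageError("round weights must be finite and non-negative")

    @property
    def alphas(self) -> np.ndarray:
        return np.array([r.alpha for r in self.rounds])


@dataclass
class PathogenicityPrediction:
    """Per-variant probability of pathogenicity and three-way clinical call."""

    variant_id: str
    pr: float
    call: str  # disease-causing | indeterminate | benign


def _impute(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = np.array(X, dtype=float)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(medians, X.shape)[nan]
    return X


def fit_adaboost(
    train: LabeledDataset,
    n_rounds: int = 500,
    tree_depth: int = 3,
    seed: int = 0,
) -> BoostModel:
    """Train the discrete AdaBoost ensemble on a labeled dataset.

    Parameters
    ----------
    train
        Labeled dataset with both classes present.
    n_rounds
        Maximum number of boosting rounds (trees).
    tree_depth
        Maximum depth of each weak-learner tree.
    seed
        Seeds the per-round tree fitting (tie-breaking inside CART).
    """
    if train.labels is None:
        raise UsageError("training requires a labeled dataset")
    if n_rounds < 1 or tree_depth < 1:
        raise UsageError("n_rounds and tree_depth must be >= 1")
    y = train.labels
    if len(np.unique(y)) < 2:
        raise UsageError("training data must contain both classes")

    medians = np.nanmedian(train.features, axis=0)
    if np.isnan(medians).any():
        logger.warning("feature(s) entirely missing in training data; imputing 0")
        medians = np.nan_to_num(medians, nan=0.0)
    X = _impute(train.features, medians)

    if (X.std(axis=0) == 0).all():
        logger.warning("all features constant; fitted trees will be trivial")

    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    rounds: list[BoostRound] = []
    stopping = "completed"
    seeds = np.random.SeedSequence(seed).generate_state(n_rounds)
    for m in range(n_rounds):
        tree = DecisionTreeClassifier(
            max_depth=tree_depth, random_state=int(seeds[m] % (2**31))
        )
        tree.fit(X, y, sample_weight=w)
        pred = tree.predict(X)
        mis = pred != y
        eps = float(w[mis].sum())
        if eps <= 0.0:
            rounds.append(BoostRound(_tree_to_nodes(tree), ALPHA_CAP, 0.0))
            stopping = "perfect_round"
            break
        if eps >= 0.5:
            stopping = "weak_learner_at_chance"
            if not rounds:
                # keep an uninformative round so the model object is valid;
                # alpha 0 makes it carry no vote (Pr falls back to 0.5)
                logger.warning("first weak learner no better than chance; model is uninformative")
                rounds.append(BoostRound(_tree_to_nodes(tree), 0.0, eps))
            break
        alpha = 0.5 * math.log((1.0 - eps) / eps)
        rounds.append(BoostRound(_tree_to_nodes(tree), alpha, eps))
        w[mis] *= math.exp(2.0 * alpha)
        w /= w.sum()

    return BoostModel(
        schema=train.schema,
        imputation=medians,
        rounds=rounds,
        n_rounds_requested=n_rounds,
        tree_depth=tree_depth,
        seed=seed,
        stopping_reason=stopping,
    )


def predict_pr(model: BoostModel, features: np.ndarray | LabeledDataset) -> np.ndarray:
    """Probability of pathogenicity for each row: the normalized weighted vote."""
    if isinstance(features, LabeledDataset):
        if features.schema.names != model.schema.names:
            bad = next(
                (
                    n
                    for n, m in zip(features.schema.names, model.schema.names)
                    if n != m
                ),
                "(column count)",
            )
            raise SchemaError(f"dataset schema does not match model schema at '{bad}'")
        features = features.features
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.schema):
        raise SchemaError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {len(model.schema)} ('{model.schema.names[0]}', ...)"
        )
    X = _impute(X, model.imputation)
    alphas = model.alphas
    total = alphas.sum()
    if total == 0.0:
        return np.full(X.shape[0], 0.5)
    votes = np.zeros(X.shape[0])
    for r in model.rounds:
        votes += r.alpha * _nodes_predict(r.nodes, X)
    return votes / total


def predict(
    model: BoostModel,
    ds: LabeledDataset,
    upper: float = 0.9,
    lower: float = 0.1,
) -> list[PathogenicityPrediction]:
    """Per-variant predictions with three-way clinical calls."""
    from .clinical_metrics import ThresholdPair, classify_three_way

    t = ThresholdPair(upper=upper, lower=lower)
    prs = predict_pr(model, ds)
    return [
        PathogenicityPrediction(v.variant_id, float(p), classify_three_way(float(p), t))
        for v, p in zip(ds.variants, prs)
    ]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: BoostModel, path: str | Path) -> None:
    """Write the model as versioned JSON; loading reproduces predictions exactly."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "schema": model.schema.to_dict(),
        "imputation": model.imputation.tolist(),
        "rounds": [
            {"nodes": r.nodes, "alpha": r.alpha, "epsilon": r.epsilon} for r in model.rounds
        ],
        "metadata": {
            "n_rounds_requested": model.n_rounds_requested,
            "tree_depth": model.tree_depth,
            "seed": model.seed,
            "stopping_reason": model.stopping_reason,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> BoostModel:
    """Load a model written by :func:`save_model`; validates version and shape."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise ModelLoadError(f"cannot read model file {path}: {e}") from e
    if not isinstance(doc, dict) or doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"unsupported or missing format_version in {path} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    try:
        schema = FeatureSchema.from_dict(doc["schema"])
        imputation = np.asarray(doc["imputation"], dtype=float)
        if imputation.shape != (len(schema),):
            raise ModelLoadError(
                f"imputation vector length {imputation.shape} does not match "
                f"schema width {len(schema)}"
            )
        meta = doc["metadata"]
        rounds = [
            BoostRound(nodes=r["nodes"], alpha=float(r["alpha"]), epsilon=float(r["epsilon"]))
            for r in doc["rounds"]
        ]
        return BoostModel(
            schema=schema,
            imputation=imputation,
            rounds=rounds,
            n_rounds_requested=int(meta["n_rounds_requested"]),
            tree_depth=int(meta["tree_depth"]),
            seed=int(meta["seed"]),
            stopping_reason=str(meta["stopping_reason"]),
        )
    except (KeyError, TypeError, ValueError, SchemaError, UsageError) as e:
        raise ModelLoadError(f"malformed model file {path}: {e}") from e
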