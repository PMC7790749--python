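"""Nested cross-validation for choosing the classification algorithm.

The selection protocol is the one used when a predictive tool is built from a
modest curated training set: candidate algorithms are tuned in an inner
5-fold cross-validation loop (grid search maximizing an out-of-fold metric),
then compared in an outer 10-fold loop where, per outer fold, each candidate
is re-tuned on the outer-training part, refit at the chosen hyperparameters,
and scored on the held-out outer fold. The winner is the candidate with the
best mean outer-fold metric. Outer test rows are never visible to the inner
tuning, so the outer scores are honest out-of-sample estimates.

Determinism: folds and every tie-break are functions of the seed; equal mean
scores go to the earlier entry (grid order / registry order).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .boost_classifier import fit_adaboost, predict_pr
from .clinical_metrics import get_metric
from .errors import StratificationError, UsageError
from .variant_data import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass
class CandidateAlgorithm:
    """A named algorithm with a finite hyperparameter grid.

    ``factory(params, seed)`` must return an object with
    ``fit(train: LabeledDataset)`` -> fitted, and the fitted object must have
    ``predict_pr(ds: LabeledDataset) -> array of P(pathogenic) in [0, 1]``.
    """

    name: str
    grid: dict[str, list]
    factory: Callable[[dict, int], "FittableModel"]

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise UsageError(f"{self.name}: hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


class FittableModel:
    """Duck-typed contract for candidate models (see CandidateAlgorithm)."""

    def fit(self, train: LabeledDataset) -> "FittableModel":  # pragma: no cover
        raise NotImplementedError

    def predict_pr(self, ds: LabeledDataset) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def make_folds(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: per-row fold index in 0..k-1.

    Within each class, rows are shuffled (seeded) and dealt round-robin, so
    per-fold class counts differ by at most one. Deterministic under seed.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise UsageError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise StratificationError(
                f"class {cls} has {idx.size} rows; need >= k={k} for stratified folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


def inner_tune(
    alg: CandidateAlgorithm,
    train: LabeledDataset,
    k: int = 5,
    metric: str = "pr_auc",
    seed: int = 0,
) -> dict:
    """Grid search maximizing the mean k-fold out-of-fold metric.

    Ties go to the earlier grid point; a grid point whose fit fails anywhere
    is scored -inf and logged, never fatal.
    """
    if train.labels is None:
        raise UsageError("tuning requires labeled data")
    score_fn = get_metric(metric)
    folds = make_folds(train.labels, k, seed)
    best_params: Optional[dict] = None
    best_score = -np.inf
    for params in alg.grid_points():
        scores = []
        try:
            for f in range(k):
                tr = train.subset(np.flatnonzero(folds != f))
                te = train.subset(np.flatnonzero(folds == f))
                model = alg.factory(params, seed).fit(tr)
                scores.append(score_fn(te.labels, model.predict_pr(te)))
            mean = float(np.mean(scores))
        except Exception as e:
            logger.warning("%s: grid point %s failed (%s); scored -inf", alg.name, params, e)
            mean = -np.inf
        if mean > best_score:  # strict: first grid point wins ties
            best_score = mean
            best_params = params
    if best_params is None:  # every grid point failed
        best_params = alg.grid_points()[0]
    return best_params


@dataclass
class AlgorithmReport:
    """Outer-fold results for one candidate."""

    name: str
    outer_scores: list[float]
    mean_score: float
    sd_score: float
    chosen_params: list[dict]  # per outer fold


@dataclass
class SelectionReport:
    """Full nested-CV comparison: per-algorithm scores and the winner."""

    algorithms: list[AlgorithmReport]
    winner: str
    metric: str
    outer_k: int
    inner_k: int
    seed: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "winner": self.winner,
                "metric": self.metric,
                "outer_k": self.outer_k,
                "inner_k": self.inner_k,
                "seed": self.seed,
                "algorithms": [
                    {
                        "name": a.name,
                        "outer_scores": a.outer_scores,
                        "mean_score": a.mean_score,
                        "sd_score": a.sd_score,
                        "chosen_params": a.chosen_params,
                    }
                    for a in self.algorithms
                ],
            },
            indent=indent,
            sort_keys=True,
        )


def nested_select(
    registry: Sequence[CandidateAlgorithm],
    train: LabeledDataset,
    outer_k: int = 10,
    inner_k: int = 5,
    metric: str = "pr_auc",
    seed: int = 0,
) -> SelectionReport:
    """Outer-k comparison of inner-tuned candidates; winner = best mean metric."""
    if not registry:
        raise UsageError("candidate registry must be non-empty")
    if train.labels is None:
        raise UsageError("selection requires labeled data")
    score_fn = get_metric(metric)
    outer_folds = make_folds(train.labels, outer_k, seed)
    # one independent seed per (outer fold) for inner folding and fitting
    fold_seeds = np.random.SeedSequence(seed).generate_state(outer_k) % (2**31)

    reports = []
    for alg in registry:
        outer_scores: list[float] = []
        chosen: list[dict] = []
        for f in range(outer_k):
            tr = train.subset(np.flatnonzero(outer_folds != f))
            te = train.subset(np.flatnonzero(outer_folds == f))
            params = inner_tune(alg, tr, k=inner_k, metric=metric, seed=int(fold_seeds[f]))
            model = alg.factory(params, int(fold_seeds[f])).fit(tr)
            outer_scores.append(float(score_fn(te.labels, model.predict_pr(te))))
            chosen.append(params)
        reports.append(
            AlgorithmReport(
                name=alg.name,
                outer_scores=outer_scores,
                mean_score=float(np.mean(outer_scores)),
                sd_score=float(np.std(outer_scores, ddof=1)),
                chosen_params=chosen,
            )
        )

    best = max(range(len(reports)), key=lambda i: (reports[i].mean_score, -i))
    return SelectionReport(
        algorithms=reports,
        winner=reports[best].name,
        metric=metric,
        outer_k=outer_k,
        inner_k=inner_k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Default candidate registry
# ---------------------------------------------------------------------------

class _BoostCandidate(FittableModel):
    """Our boosted-tree classifier as a selection candidate."""

    def __init__(self, params: dict, seed: int):
        self.params = params
        self.seed = seed
        self.model = None

    def fit(self, train: LabeledDataset) -> "_BoostCandidate":
        self.model = fit_adaboost(
            train,
            n_rounds=self.params.get("n_rounds", 100),
            tree_depth=self.params.get("tree_depth", 3),
            seed=self.seed,
        )
        return self

    def predict_pr(self, ds: LabeledDataset) -> np.ndarray:
        return predict_pr(self.model, ds)


class _SklearnCandidate(FittableModel):
    """Adapter: median-imputed sklearn pipeline with predict_proba."""

    def __init__(self, estimator: BaseEstimator):
        from sklearn.impute import SimpleImputer
        from sklearn.pipeline import Pipeline

        self.pipe = Pipeline(
            [("impute", SimpleImputer(strategy="median")), ("clf", estimator)]
        )

    def fit(self, train: LabeledDataset) -> "_SklearnCandidate":
        self.pipe.fit(train.features, train.labels)
        return self

    def predict_pr(self, ds: LabeledDataset) -> np.ndarray:
        proba = self.pipe.predict_proba(ds.features)
        cls = list(self.pipe.named_steps["clf"].classes_)
        return proba[:, cls.index(1)]


class MajorityClassBaseline(FittableModel):
    """Predicts the training prevalence of the pathogenic class for all rows."""

    def __init__(self, params: dict | None = None, seed: int = 0):
        self.prevalence = 0.5

    def fit(self, train: LabeledDataset) -> "MajorityClassBaseline":
        self.prevalence = float(np.mean(train.labels))
        return self

    def predict_pr(self, ds: LabeledDataset) -> np.ndarray:
        return np.full(len(ds), self.prevalence)


def boosting_candidate(
    n_rounds: Sequence[int] = (50, 100), tree_depth: Sequence[int] = (1, 3)
) -> CandidateAlgorithm:
    return CandidateAlgorithm(
        name="adaboost",
        grid={"n_rounds": list(n_rounds), "tree_depth": list(tree_depth)},
        factory=lambda params, seed: _BoostCandidate(params, seed),
    )


def baseline_candidate() -> CandidateAlgorithm:
    return CandidateAlgorithm(
        name="majority_baseline",
        grid={"dummy": [0]},
        factory=lambda params, seed: MajorityClassBaseline(params, seed),
    )


def default_registry(small: bool = False) -> list[CandidateAlgorithm]:
    """Nine-candidate registry spanning the major algorithm families.

    These stand in for a typical best-in-class-per-family comparison:
    boosted trees (ours), random forest, L2 logistic regression, RBF SVM,
    k-nearest-neighbour, Gaussian naive Bayes, a single CART tree, gradient
    boosting and a small feed-forward network. Only the boosted-tree entry's
    behaviour is contractually specified elsewhere; the rest exist so the
    selection machinery has a realistic field to compare. ``small=True``
    shrinks every grid to one point for quick runs.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    def sk(name: str, grid: dict, build: Callable[[dict, int], BaseEstimator]):
        return CandidateAlgorithm(
            name=name,
            grid={k: v[:1] for k, v in grid.items()} if small else grid,
            factory=lambda params, seed: _SklearnCandidate(build(params, seed)),
        )

    return [
        boosting_candidate(
            n_rounds=(50,) if small else (50, 100), tree_depth=(3,) if small else (1, 3)
        ),
        sk(
            "random_forest",
            {"n_estimators": [100, 300]},
            lambda p, s: RandomForestClassifier(n_estimators=p["n_estimators"], random_state=s),
        ),
        sk(
            "logistic_l2",
            {"C": [0.1, 1.0, 10.0]},
            lambda p, s: LogisticRegression(C=p["C"], max_iter=2000),
        ),
        sk(
            "svm_rbf",
            {"C": [1.0, 10.0]},
            lambda p, s: SVC(C=p["C"], probability=True, random_state=s),
        ),
        sk(
            "knn",
            {"n_neighbors": [5, 15]},
            lambda p, s: KNeighborsClassifier(n_neighbors=p["n_neighbors"]),
        ),
        sk("naive_bayes", {"var_smoothing": [1e-9]}, lambda p, s: GaussianNB(var_smoothing=p["var_smoothing"])),
        sk(
            "decision_tree",
            {"max_depth": [3, 6]},
            lambda p, s: DecisionTreeClassifier(max_depth=p["max_depth"], random_state=s),
        ),
        sk(
            "gradient_boosting",
            {"n_estimators": [100], "max_depth": [3]},
            lambda p, s: GradientBoostingClassifier(
                n_estimators=p["n_estimators"], max_depth=p["max_depth"], random_state=s
            ),
        ),
        sk(
            "mlp",
            {"hidden_layer_sizes": [(32,), (64,)]},
            lambda p, s: MLPClassifier(
                hidden_layer_sizes=p["hidden_layer_sizes"], max_iter=500, random_state=s
            ),
        ),
    ]
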