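"""The pool of baseline classifiers: 10 algorithm families x N descriptors.

Each (descriptor, algorithm) pair is one baseline model. Six families (ET,
LR, MLP, RF, SVM, XGB) are tuned over a small grid by cross-validated MCC;
DT, KNN, NB and PLS use library defaults. The full 13-descriptor pool has
130 members, kept in fixed descriptor-major, algorithm-minor order.

SVM probabilities come from Platt-style sigmoid calibration wrapped around
the margin classifier; PLS has no native classifier, so it regresses on
{0,1} targets and clips the output to [0,1] as a probability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .evalmetrics import (
    EvalMetrics,
    crossvalidate,
)

ALGORITHMS = ("DT", "ET", "KNN", "LR", "MLP", "NB", "PLS", "RF", "SVM", "XGB")
TUNED_ALGORITHMS = frozenset({"ET", "LR", "MLP", "RF", "SVM", "XGB"})

#: Default hyperparameter search grids for the tuned families. Grid order is
#: the documented enumeration order used for deterministic tie-breaking.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 200, 500], "max_features": ["sqrt", "log2"]},
    "ET": {"n_estimators": [100, 200, 500], "max_features": ["sqrt", "log2"]},
    "SVM": {
        "C": [2.0**e for e in range(-5, 6)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
    },
    "LR": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "MLP": {"hidden_layer_sizes": [(32,), (64,), (128,)], "alpha": [1e-4, 1e-3]},
    "XGB": {
        "max_depth": [3, 5, 7],
        "learning_rate": [0.05, 0.1, 0.3],
        "n_estimators": [100, 300],
    },
}


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares regression adapted to binary classification.

    Fits PLS regression on {0,1} targets; the clipped response is the
    probability of the positive class and the label is probability > 0.5.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.array([0, 1])
        ncomp = int(min(self.n_components, X.shape[1], max(1, X.shape[0] - 1)))
        self.pls_ = PLSRegression(n_components=ncomp)
        self.pls_.fit(X, y)
        return self

    def predict_proba(self, X):
        p = np.clip(self.pls_.predict(np.asarray(X, dtype=float)).ravel(), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass(frozen=True)
class BaselineSpec:
    """One (algorithm, descriptor) cell of the baseline-model grid."""

    algorithm: str
    descriptor: str
    hyperparameter_grid: Mapping[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def name(self) -> str:
        return f"{self.algorithm}-{self.descriptor}"


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    chosen_params: dict
    cv_metrics: EvalMetrics
    model: object  # fitted classifier exposing predict_proba


@dataclass
class BaselinePool:
    """Ordered collection of fitted baselines (descriptor-major, algorithm-minor)."""

    members: list[FittedBaseline]
    descriptors: tuple[str, ...]
    folds: int
    seed: int

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_names(self) -> list[str]:
        return [m.spec.name for m in self.members]

    def metrics_table(self) -> pd.DataFrame:
        """Per-baseline cross-validation metric table (report companion)."""
        rows = []
        for m in self.members:
            rows.append(
                {
                    "model": m.spec.name,
                    "algorithm": m.spec.algorithm,
                    "descriptor": m.spec.descriptor,
                    "acc": m.cv_metrics.acc,
                    "sn": m.cv_metrics.sn,
                    "sp": m.cv_metrics.sp,
                    "mcc": m.cv_metrics.mcc,
                    "auc": m.cv_metrics.auc,
                }
            )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        manifest = {
            "descriptors": list(self.descriptors),
            "members": self.member_names,
            "folds": self.folds,
            "seed": self.seed,
        }
        joblib.dump({"manifest": manifest, "pool": self}, path)

    @staticmethod
    def load(path) -> "BaselinePool":
        return joblib.load(path)["pool"]


def make_classifier(spec: BaselineSpec, params: Mapping | None = None):
    """Instantiate an unfitted probability classifier for a baseline spec.

    All stochastic learners receive ``spec.seed``; parallelism is disabled
    for bit-for-bit reproducibility.
    """
    p = dict(params or {})
    seed = spec.seed
    alg = spec.algorithm
    if alg == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if alg == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **p)
    if alg == "KNN":
        return KNeighborsClassifier(**p)
    if alg == "LR":
        p.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **p)
    if alg == "MLP":
        p.setdefault("max_iter", 300)
        return MLPClassifier(random_state=seed, **p)
    if alg == "NB":
        return GaussianNB(**p)
    if alg == "PLS":
        return PLSClassifier(**p)
    if alg == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if alg == "SVM":
        # RBF SVM with Platt-style sigmoid calibration for probabilities
        return CalibratedClassifierCV(
            SVC(random_state=seed, **p), method="sigmoid", cv=3
        )
    if alg == "XGB":
        p.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, n_jobs=1, **p)
    raise ValueError(f"unknown algorithm {alg!r}")


def grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    """Enumerate a grid in documented order (insertion order of keys)."""
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune_baseline(
    spec: BaselineSpec,
    features: np.ndarray,
    labels: Sequence[int],
    folds: int = 10,
    seed: int | None = None,
) -> FittedBaseline:
    """Fit one baseline: grid-search by cross-validated MCC, refit on all data.

    Untuned families (DT, KNN, NB, PLS) carry an empty grid and evaluate only
    their defaults; ties in the grid are broken by enumeration order (first
    wins). An explicit grid on a spec is always honored.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError(f"{spec.name}: features and labels misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError(f"{spec.name}: both classes must be present")
    if seed is not None:
        spec = BaselineSpec(spec.algorithm, spec.descriptor, spec.hyperparameter_grid, seed)
    grid = spec.hyperparameter_grid
    best_params, best_metrics = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in grid_points(grid):
            m = crossvalidate(
                lambda: make_classifier(spec, params), X, y, folds=folds, seed=spec.seed
            )
            if best_metrics is None or m.mcc > best_metrics.mcc:
                best_params, best_metrics = params, m
        model = make_classifier(spec, best_params)
        model.fit(X, y)
    return FittedBaseline(
        spec=spec, chosen_params=best_params, cv_metrics=best_metrics, model=model
    )


def train_pool(
    features_by_descriptor: Mapping[str, pd.DataFrame],
    labels: Sequence[int],
    seed: int = 0,
    folds: int = 10,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
) -> BaselinePool:
    """Train the full baseline pool over every (descriptor, algorithm) pair.

    ``grids`` overrides the default search grids per algorithm. All feature
    matrices must be row-aligned to the same records.
    """
    grids = dict(DEFAULT_GRIDS if grids is None else grids)
    y = np.asarray(labels, dtype=int)
    descriptors = tuple(features_by_descriptor)
    index = None
    for desc, frame in features_by_descriptor.items():
        if frame.shape[0] != len(y):
            raise ValueError(f"{desc}: {frame.shape[0]} rows for {len(y)} labels")
        if index is None:
            index = frame.index
        elif not frame.index.equals(index):
            raise ValueError(f"{desc}: row index misaligned with other descriptors")
    members = []
    for desc in descriptors:
        X = features_by_descriptor[desc].to_numpy(dtype=float)
        for alg in algorithms:
            spec = BaselineSpec(alg, desc, grids.get(alg, {}), seed=seed)
            members.append(tune_baseline(spec, X, y, folds=folds))
    return BaselinePool(members=members, descriptors=descriptors, folds=folds, seed=seed)
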