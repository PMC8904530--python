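"""Stacked generalization over the baseline pool.

Every baseline model contributes one meta-feature column: its probability
that a protein is a virion protein. Three meta representations are built
from the pool — PF (probabilistic features, the raw probabilities), CF
(class features, PF thresholded at strictly > 0.5) and PCF (their
concatenation). Training-set PF columns are produced out-of-fold so no
sample is scored by a model that saw it (standard stacking leakage control;
an in-sample mode exists behind a flag).

A two-step selection then prunes the meta features: a gradient-boosted tree
classifier ranks columns by gain importance, and top-k subsets (k = 5..100
step 5 by default) are swept with a small random-forest meta-model tuned by
cross-validated MCC. The final model is the meta random forest fit on the
chosen columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .evalmetrics import (
    evaluate,
    out_of_fold_probabilities,
    positive_probability,
    stratified_folds,
)
from .models import BaselinePool, make_classifier
from .seqio import ProteinRecord, PssmProfile
from .descriptors import encode_all

DEFAULT_K_GRID = tuple(range(5, 101, 5))

#: Meta random-forest tuning grid (searched per subset size by CV MCC).
DEFAULT_META_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_features": ["sqrt", "log2"],
}


@dataclass
class MetaFeatureMatrix:
    """n x d meta-feature matrix of kind PF, CF or PCF."""

    kind: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("PF", "CF", "PCF"):
            raise ValueError(f"kind must be PF/CF/PCF, got {self.kind!r}")
        vals = self.frame.to_numpy(dtype=float)
        if self.kind == "PF" and ((vals < 0) | (vals > 1)).any():
            raise ValueError("PF values must lie in [0, 1]")
        if self.kind == "CF" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("CF values must be 0 or 1")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class SelectionResult:
    """Outcome of the two-step feature selection."""

    ranking: np.ndarray  # permutation of column indices, most important first
    column_names: list[str]
    k_grid: tuple[int, ...]
    per_k_mcc: dict[int, float]
    per_k_params: dict[int, dict]
    chosen_k: int

    @property
    def chosen_indices(self) -> np.ndarray:
        return self.ranking[: self.chosen_k]

    @property
    def chosen_columns(self) -> list[str]:
        return [self.column_names[i] for i in self.chosen_indices]

    @property
    def chosen_params(self) -> dict:
        return self.per_k_params[self.chosen_k]


@dataclass
class StackedModel:
    """The final stacked predictor: pool + selection + meta random forest."""

    pool: BaselinePool
    selection: SelectionResult
    meta: RandomForestClassifier
    kind: str = "PF"
    threshold: float = 0.5
    encode_kwargs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "StackedModel":
        return joblib.load(path)


def _pf_frame(pool: BaselinePool, matrix: np.ndarray, index) -> MetaFeatureMatrix:
    frame = pd.DataFrame(matrix, index=index, columns=pool.member_names)
    return MetaFeatureMatrix("PF", frame)


def generate_pf(
    pool: BaselinePool,
    features_by_descriptor: Mapping[str, pd.DataFrame],
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    mode: str = "out-of-fold",
) -> MetaFeatureMatrix:
    """Training-set probabilistic features, one column per pool member.

    ``out-of-fold`` (default) refits each member's configuration within
    stratified folds so a sample's PF entry never comes from a model fitted
    on that sample. ``in-sample`` scores the training data with the fully
    fitted members instead.
    """
    if mode not in ("out-of-fold", "in-sample"):
        raise ValueError(f"unknown PF mode {mode!r}")
    y = np.asarray(labels, dtype=int)
    index = None
    for desc in pool.descriptors:
        if desc not in features_by_descriptor:
            raise ValueError(f"missing feature matrix for descriptor {desc!r}")
        frame = features_by_descriptor[desc]
        if frame.shape[0] != len(y):
            raise ValueError(f"{desc}: rows misaligned with labels")
        index = frame.index if index is None else index
    cols = np.empty((len(y), len(pool.members)))
    assignment = stratified_folds(y, folds, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, member in enumerate(pool.members):
            X = features_by_descriptor[member.spec.descriptor].to_numpy(dtype=float)
            if mode == "in-sample":
                cols[:, j] = positive_probability(member.model, X)
            else:
                cols[:, j] = out_of_fold_probabilities(
                    lambda m=member: make_classifier(m.spec, m.chosen_params),
                    X,
                    y,
                    folds=folds,
                    seed=seed,
                    fold_assignment=assignment,
                )
    return _pf_frame(pool, cols, index)


def pf_for_new_data(
    pool: BaselinePool, features_by_descriptor: Mapping[str, pd.DataFrame]
) -> MetaFeatureMatrix:
    """Probabilistic features for unseen samples from the fully fitted pool."""
    index = None
    n = None
    for desc in pool.descriptors:
        if desc not in features_by_descriptor:
            raise ValueError(f"missing feature matrix for descriptor {desc!r}")
        frame = features_by_descriptor[desc]
        if n is None:
            n, index = frame.shape[0], frame.index
        elif frame.shape[0] != n:
            raise ValueError(f"{desc}: rows misaligned across descriptors")
    cols = np.empty((n, len(pool.members)))
    for j, member in enumerate(pool.members):
        X = features_by_descriptor[member.spec.descriptor].to_numpy(dtype=float)
        cols[:, j] = positive_probability(member.model, X)
    return _pf_frame(pool, cols, index)


def binarize_cf(pf: MetaFeatureMatrix, threshold: float = 0.5) -> MetaFeatureMatrix:
    """Class features: 1 where the probability is strictly above the threshold."""
    if pf.kind != "PF":
        raise ValueError("binarize_cf expects a PF matrix")
    frame = (pf.frame > threshold).astype(float)
    frame.columns = [f"{c}.CF" for c in pf.frame.columns]
    return MetaFeatureMatrix("CF", frame)


def concat_pcf(pf: MetaFeatureMatrix, cf: MetaFeatureMatrix) -> MetaFeatureMatrix:
    """PF and CF side by side (PF block first)."""
    if pf.kind != "PF" or cf.kind != "CF":
        raise ValueError("concat_pcf expects (PF, CF)")
    if pf.frame.shape[0] != cf.frame.shape[0]:
        raise ValueError("PF and CF row counts differ")
    if cf.frame.shape[1] != pf.frame.shape[1]:
        raise ValueError("PF and CF column counts differ")
    frame = pd.concat([pf.frame, cf.frame.set_index(pf.frame.index)], axis=1)
    return MetaFeatureMatrix("PCF", frame)


def build_meta_features(pf: MetaFeatureMatrix, kind: str) -> MetaFeatureMatrix:
    """Derive the requested meta representation from a PF matrix."""
    if kind == "PF":
        return pf
    cf = binarize_cf(pf)
    if kind == "CF":
        return cf
    if kind == "PCF":
        return concat_pcf(pf, cf)
    raise ValueError(f"unknown meta-feature kind {kind!r}")


def rank_features(
    meta_features: MetaFeatureMatrix, labels: Sequence[int], seed: int = 0
) -> np.ndarray:
    """Rank meta-feature columns by gradient-boosted-tree gain importance.

    Returns a full permutation of column indices, most important first;
    columns never used by the booster score 0 and ties break by index.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking needs both classes present")
    X = meta_features.values
    model = XGBClassifier(
        random_state=seed, n_jobs=1, eval_metric="logloss", importance_type="gain"
    )
    model.fit(X, y)
    scores = model.get_booster().get_score(importance_type="gain")
    gains = np.zeros(X.shape[1])
    for feat, g in scores.items():
        gains[int(feat[1:])] = g
    # stable argsort on -gain: ties resolve to the lower column index
    return np.argsort(-gains, kind="stable")


def _tune_meta_rf(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
    meta_grid: Mapping[str, Sequence],
) -> tuple[dict, float]:
    """Best (params, pooled CV MCC) of the meta random forest on X."""
    from .models import grid_points

    best = None
    for params in grid_points(meta_grid):
        oof = out_of_fold_probabilities(
            lambda p=params: RandomForestClassifier(random_state=seed, n_jobs=1, **p),
            X,
            y,
            folds=folds,
            seed=seed,
        )
        mcc = evaluate(y, oof).mcc
        if best is None or mcc > best[1]:
            best = (params, mcc)
    return best


def sweep_subsets(
    meta_features: MetaFeatureMatrix,
    labels: Sequence[int],
    ranking: np.ndarray,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    folds: int = 10,
    seed: int = 0,
    meta_grid: Mapping[str, Sequence] | None = None,
) -> SelectionResult:
    """Sweep top-k meta-feature subsets; keep the CV-MCC-maximal size.

    For each k the meta random forest is tuned (grid by pooled CV MCC) on the
    top-k ranked columns. Ties across k go to the smallest subset. Grid
    values exceeding the column count are dropped with a warning.
    """
    y = np.asarray(labels, dtype=int)
    X = meta_features.values
    d = X.shape[1]
    meta_grid = DEFAULT_META_GRID if meta_grid is None else meta_grid
    ks = [int(k) for k in k_grid]
    if any(k <= 0 for k in ks):
        raise ValueError("subset sizes must be positive")
    usable = [k for k in ks if k <= d]
    if len(usable) < len(ks):
        warnings.warn(
            f"dropping subset sizes > {d} available columns: "
            f"{sorted(set(ks) - set(usable))}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("empty subset-size grid after filtering")
    per_k_mcc: dict[int, float] = {}
    per_k_params: dict[int, dict] = {}
    for k in usable:
        params, mcc = _tune_meta_rf(X[:, ranking[:k]], y, folds, seed, meta_grid)
        per_k_mcc[k] = mcc
        per_k_params[k] = params
    chosen_k = max(sorted(usable), key=lambda k: per_k_mcc[k])
    # max() with sorted keys returns the first maximum -> smallest k on ties
    return SelectionResult(
        ranking=np.asarray(ranking),
        column_names=meta_features.columns,
        k_grid=tuple(usable),
        per_k_mcc=per_k_mcc,
        per_k_params=per_k_params,
        chosen_k=chosen_k,
    )


def fit_stacked(
    pool: BaselinePool,
    meta_features: MetaFeatureMatrix,
    labels: Sequence[int],
    selection: SelectionResult,
    seed: int = 0,
    encode_kwargs: Mapping | None = None,
) -> StackedModel:
    """Fit the meta random forest on the selected columns of the meta features."""
    if selection.column_names != meta_features.columns:
        raise ValueError("selection was computed on different meta-feature columns")
    y = np.asarray(labels, dtype=int)
    X = meta_features.values[:, selection.chosen_indices]
    meta = RandomForestClassifier(random_state=seed, n_jobs=1, **selection.chosen_params)
    meta.fit(X, y)
    return StackedModel(
        pool=pool,
        selection=selection,
        meta=meta,
        kind=meta_features.kind,
        encode_kwargs=dict(encode_kwargs or {}),
    )


def predict_meta(model: StackedModel, pf: MetaFeatureMatrix) -> np.ndarray:
    """Meta-model probability of the positive class from a PF matrix."""
    feats = build_meta_features(pf, model.kind)
    X = feats.values[:, model.selection.chosen_indices]
    return positive_probability(model.meta, X)


def predict_stacked(
    model: StackedModel,
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, PssmProfile] | None = None,
) -> pd.DataFrame:
    """Score raw sequences end-to-end.

    Encodes the records with the pool's descriptors, featurizes them through
    the fitted pool and applies the meta model. Returns a DataFrame with
    columns ``probability`` and ``label`` (probability > threshold), indexed
    by record id.
    """
    feats = encode_all(
        records,
        profiles,
        descriptor_list=model.pool.descriptors,
        **model.encode_kwargs,
    )
    pf = pf_for_new_data(model.pool, feats)
    prob = predict_meta(model, pf)
    return pd.DataFrame(
        {"probability": prob, "label": (prob > model.threshold).astype(int)},
        index=[r.id for r in records],
    )
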