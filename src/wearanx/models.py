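"""Feature-based classifiers, the cross-validation harness, and feature
importance aggregation.

Seven model families are supported: Decision Tree (DT), Random Forest (RF),
Linear Discriminant Analysis (LDA), k-nearest neighbours (KNN), AdaBoost
(AB), Support Vector Machine (SVM) and gradient-boosted trees (XGB; backed
by sklearn's ``GradientBoostingClassifier``).  The evaluation protocol is
stratified 5-fold cross-validation where, for each held-out test fold, the
remaining rows are split 80/20 into training and validation sets; a small
per-family hyperparameter grid is selected on the validation split, the
selected model is scored on the test fold, and the whole procedure repeats
for several seeded iterations.

Importance extraction depends on the family: impurity importances for tree
ensembles, absolute standardized coefficients for the linear models, and
seeded permutation importance for KNN and kernel SVM.  Per-model importance
vectors are combined by squaring each feature's importance within a model,
summing over models, and normalizing — which up-weights features that are
consistently influential across families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    NotFittedError,
    StratificationError,
)
from .features import META_COLUMNS

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "EvalResult",
    "AnxietyClassifier",
    "crossval_evaluate",
    "feature_importances",
    "aggregate_importance",
    "modality_rollup",
    "importance_entropy",
]

MODEL_FAMILIES = ("DT", "RF", "LDA", "KNN", "AB", "SVM", "XGB")

#: minimal per-family grids explored on the 80/20 inner validation split
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "DT": [{"max_depth": None}, {"max_depth": 5}],
    "RF": [{}],
    "LDA": [{}],
    "KNN": [{"n_neighbors": 5}, {"n_neighbors": 11}],
    "AB": [{}],
    "SVM": [{"C": 1.0}, {"C": 10.0}],
    "XGB": [{}],
}


@dataclass
class ModelSpec:
    family: str = "RF"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise InvalidInputError(
                f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")


@dataclass
class EvalResult:
    family: str
    per_fold: list[tuple[float, float]]       # (accuracy, f1) per evaluated fold
    mean_accuracy: float
    mean_f1: float
    importance: pd.Series | None = None       # normalized, sums to 1 when defined


def _build_estimator(family: str, seed: int, params: dict):
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **params)
    if family == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if family == "KNN":
        return Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(**({"n_neighbors": 5} | params)))])
    if family == "AB":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "SVM":
        return Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf", random_state=seed,
                                     **({"C": 1.0} | params)))])
    if family == "XGB":
        # gradient-boosted trees; sklearn backend
        return GradientBoostingClassifier(random_state=seed, **params)
    raise InvalidInputError(f"unknown family {family!r}")


class AnxietyClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-compatible binary anxiety classifier over named features.

    Parameters
    ----------
    family : str
        One of :data:`MODEL_FAMILIES`.
    seed : int
        Random state for the underlying estimator.
    hyperparameters : dict
        Family-specific overrides passed to the backend estimator.

    After ``fit``, ``estimator_`` holds the fitted backend, ``classes_`` the
    class labels, ``feature_names_in_`` the training schema (when fitted on a
    DataFrame) and ``feature_std_`` the per-feature training standard
    deviation (used for standardized linear coefficients).
    """

    def __init__(self, family: str = "RF", seed: int = 0,
                 hyperparameters: dict | None = None):
        self.family = family
        self.seed = seed
        self.hyperparameters = hyperparameters

    def fit(self, X, y):
        if self.family not in MODEL_FAMILIES:
            raise InvalidInputError(f"unknown family {self.family!r}")
        params = dict(self.hyperparameters or {})
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(Xv.shape[1])], dtype=object)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise StratificationError("training data contains a single class")
        self.estimator_ = _build_estimator(self.family, self.seed, params)
        self.estimator_.fit(Xv, y)
        self.classes_ = np.unique(y)
        self.feature_std_ = Xv.std(axis=0)
        self.n_features_in_ = Xv.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "estimator_"):
            raise NotFittedError("call fit before predict/score")

    def _align(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                from .exceptions import SchemaError

                raise SchemaError(f"missing features at predict time: {missing}")
            return X.loc[:, list(self.feature_names_in_)].to_numpy(float)
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            from .exceptions import SchemaError

            raise SchemaError("feature count mismatch")
        return X

    def predict(self, X):
        self._check_fitted()
        return self.estimator_.predict(self._align(X))

    def score(self, X, y):
        return accuracy_score(y, self.predict(X))


def split_features(table: pd.DataFrame, label_col: str = "label"
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Separate the feature matrix from labels, dropping metadata columns."""
    if label_col not in table.columns:
        raise InvalidInputError(f"table lacks label column {label_col!r}")
    drop = [c for c in META_COLUMNS if c in table.columns]
    X = table.drop(columns=drop)
    return X, table[label_col].to_numpy()


def feature_importances(clf: AnxietyClassifier, X=None, y=None, *,
                        n_repeats: int = 20, seed: int = 0) -> pd.Series:
    """Normalized importance vector for a fitted classifier.

    Tree families use impurity importances; LDA and linear-kernel SVM use
    absolute coefficients standardized by the training feature scale; KNN and
    kernel SVM use permutation importance (``n_repeats`` seeded shuffles on
    the supplied data, negative contributions clipped at zero).  The vector
    is normalized to sum to 1; a completely uninformative vector falls back
    to uniform.
    """
    clf._check_fitted()
    est = clf.estimator_
    names = list(clf.feature_names_in_)
    family = clf.family
    if family in ("DT", "RF", "AB", "XGB"):
        raw = np.asarray(est.feature_importances_, float)
    elif family == "LDA":
        raw = np.abs(est.coef_[0]) * clf.feature_std_
    elif family == "SVM" and est.named_steps["svc"].kernel == "linear":
        raw = np.abs(est.named_steps["svc"].coef_[0])  # pipeline input is standardized
    else:  # KNN, kernel SVM -> permutation importance
        if X is None or y is None:
            raise InvalidInputError(
                f"{family} importance needs data for permutation shuffles")
        Xv = clf._align(X)
        res = permutation_importance(est, Xv, np.asarray(y), n_repeats=n_repeats,
                                     random_state=seed, scoring="accuracy")
        raw = np.clip(res.importances_mean, 0.0, None)
    total = raw.sum()
    if total <= 0:
        raw = np.full(len(names), 1.0 / len(names))
        total = 1.0
    return pd.Series(raw / total, index=names)


def crossval_evaluate(table: pd.DataFrame, spec: ModelSpec, k: int = 5,
                      iters: int = 5, seed: int | None = None, *,
                      grid: list[dict] | None = None,
                      compute_importance: bool = True,
                      label_col: str = "label") -> EvalResult:
    """Stratified k-fold evaluation with an inner 80/20 validation split.

    For each test fold the remaining rows are split 80/20 (stratified) into
    train/validation; each grid candidate is fitted on train and the one with
    the best validation accuracy is scored on the test fold.  The procedure
    repeats ``iters`` times with distinct fold seeds; accuracy and the
    anxious-class F1 are averaged over all evaluated folds.
    """
    X, y = split_features(table, label_col)
    if len(X) < k * 5:
        raise InvalidInputError(f"need at least {k * 5} rows for {k}-fold CV")
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < k:
        raise StratificationError("each class needs at least k rows")
    seed = spec.seed if seed is None else seed
    grid = grid if grid is not None else DEFAULT_GRIDS[spec.family]
    pos = int(np.max(y))  # anxious class
    per_fold: list[tuple[float, float]] = []
    importances: list[pd.Series] = []
    for it in range(iters):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + it)
        for fold, (rest_idx, test_idx) in enumerate(skf.split(X, y)):
            X_rest, y_rest = X.iloc[rest_idx], y[rest_idx]
            X_test, y_test = X.iloc[test_idx], y[test_idx]
            X_tr, X_val, y_tr, y_val = train_test_split(
                X_rest, y_rest, test_size=0.2, stratify=y_rest,
                random_state=seed + 1000 * it + fold)
            best, best_val = None, -np.inf
            for cand in grid:
                params = {**cand, **spec.hyperparameters}
                clf = AnxietyClassifier(spec.family, seed=seed,
                                        hyperparameters=params).fit(X_tr, y_tr)
                val_acc = clf.score(X_val, y_val)
                if val_acc > best_val:
                    best, best_val = clf, val_acc
            y_pred = best.predict(X_test)
            per_fold.append((
                float(accuracy_score(y_test, y_pred)),
                float(f1_score(y_test, y_pred, pos_label=pos, zero_division=0)),
            ))
            if compute_importance:
                importances.append(feature_importances(
                    best, X_tr, y_tr, seed=seed + 1000 * it + fold))
    accs = np.array([a for a, _ in per_fold])
    f1s = np.array([f for _, f in per_fold])
    imp = None
    if importances:
        imp = pd.concat(importances, axis=1).mean(axis=1)
        imp = imp / imp.sum()
    return EvalResult(family=spec.family, per_fold=per_fold,
                      mean_accuracy=float(accs.mean()), mean_f1=float(f1s.mean()),
                      importance=imp)


def aggregate_importance(matrix: pd.DataFrame | np.ndarray, *,
                         squared_denominator: bool = True) -> pd.Series | np.ndarray:
    """Weighted feature importance across models.

    Each model's importance row is renormalized to sum to 1; then
    ``s_f = sum_models i_{f,m}**2`` and the weights are ``s_f / sum_f s_f``
    (a proper distribution).  With ``squared_denominator=False`` the
    denominator is instead the raw total of importances (the alternative
    reading of the aggregation sentence; weights then need not sum to 1).
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    m = matrix.to_numpy(float) if is_frame else np.asarray(matrix, float)
    if m.ndim != 2:
        raise InvalidInputError("importance matrix must be 2-D (models x features)")
    if (m < 0).any():
        raise InvalidInputError("importances must be non-negative")
    row_sums = m.sum(axis=1)
    if not (row_sums > 0).any():
        raise DegenerateInputError("all-zero importance matrix")
    if (row_sums == 0).any():
        raise DegenerateInputError("a model row is all zero; cannot renormalize")
    rows = m / row_sums[:, None]
    s = (rows ** 2).sum(axis=0)
    denom = s.sum() if squared_denominator else rows.sum()
    w = s / denom
    if is_frame:
        return pd.Series(w, index=matrix.columns)
    return w


def modality_rollup(weights: pd.Series, feature_to_modality: dict[str, str]
                    ) -> pd.Series:
    """Sum feature weights per modality, ranked descending."""
    missing = [f for f in weights.index if f not in feature_to_modality]
    if missing:
        raise InvalidInputError(f"unmapped features: {missing}")
    modalities = sorted(set(feature_to_modality.values()))
    out = pd.Series(0.0, index=modalities)
    for f, w in weights.items():
        out[feature_to_modality[f]] += w
    return out.sort_values(ascending=False)


def importance_entropy(weights: pd.Series | np.ndarray) -> float:
    """Shannon entropy (nats) of a normalized importance vector — the
    dispersion statistic reported alongside transfer scores."""
    w = np.asarray(weights, float)
    w = w[w > 0]
    if w.size == 0:
        return 0.0
    w = w / w.sum()
    return float(-(w * np.log(w)).sum())
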