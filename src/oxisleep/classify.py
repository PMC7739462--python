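"""Maximum-margin classification of per-minute SpO2 features.

The screening model is a soft-margin SVM with a radial basis function
kernel k(x, z) = exp(-||x - z||^2 / (2 sigma^2)), penalty C = 1000 and
kernel width sigma = 5 (so gamma = 1/(2 sigma^2) = 0.02). Features are
min-max scaled to [0, 1] on the *training* data only; test-time values
outside the training range are not clipped. Evaluation uses stratified
k-fold cross-validation with pooled confusion counts, with apnea as the
positive class. An AdaBoost ensemble of decision stumps is provided as
a baseline through the same harness.

Estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``decision_function`` / ``get_params``; fitted attributes end in an
underscore) and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import FormatError, StateError, TrainingError
from .signal import LABEL_APNEA

DEFAULT_C = 1000.0
DEFAULT_SIGMA = 5.0
DEFAULT_FOLDS = 10


# ---------------------------------------------------------------------------
# feature scaling


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training min/max for the 0-1 affine map."""

    data_min: np.ndarray
    data_max: np.ndarray


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Learn per-column min/max from training rows only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise FormatError("scaler needs a non-empty 2-D matrix")
    return ScalerParams(data_min=X.min(axis=0), data_max=X.max(axis=0))


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    """Map column j through (x - min_j) / (max_j - min_j).

    Constant training columns map to 0 (unit denominator convention);
    out-of-range test values extrapolate linearly — no clipping.
    """
    if params is None:
        raise StateError("scaler applied before fitting")
    X = np.asarray(X, dtype=float)
    rng = params.data_max - params.data_min
    denom = np.where(rng > 0, rng, 1.0)
    return (X - params.data_min) / denom


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainingConfig:
    """Hyperparameters and evaluation protocol knobs."""

    C: float = DEFAULT_C
    sigma: float = DEFAULT_SIGMA
    folds: int = DEFAULT_FOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise TrainingError(f"C must be > 0, got {self.C}")
        if not self.sigma > 0:
            raise TrainingError(f"sigma must be > 0, got {self.sigma}")
        if self.folds < 2:
            raise TrainingError(f"folds must be >= 2, got {self.folds}")

    @property
    def gamma(self) -> float:
        """RBF exponent coefficient, 1 / (2 sigma^2)."""
        return 1.0 / (2.0 * self.sigma**2)

    def to_dict(self) -> dict:
        return {"C": self.C, "sigma": self.sigma, "folds": self.folds, "seed": self.seed}


# ---------------------------------------------------------------------------
# estimators


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise TrainingError(
            f"training requires exactly two classes, got {classes.tolist()}"
        )
    return classes


class SpO2SVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel soft-margin SVM with built-in 0-1 feature scaling.

    Parameters
    ----------
    C : float
        Slack penalty of the soft-margin objective.
    sigma : float
        RBF kernel width; gamma = 1 / (2 sigma^2).

    The decision function h(x) is >= 0 for the second (larger) class
    label; with the package encoding (+1 normal, -1 apnea) a tie at
    exactly 0 therefore predicts normal. After ``fit`` the model is
    self-contained (scaler bounds, support vectors, dual coefficients,
    intercept), so it serialises to JSON and predicts without sklearn
    internals.
    """

    def __init__(self, C: float = DEFAULT_C, sigma: float = DEFAULT_SIGMA):
        self.C = C
        self.sigma = sigma

    @property
    def gamma_(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise FormatError("X must be 2-D with one row per label")
        self.classes_ = _check_two_classes(y)
        self.scaler_ = fit_scaler(X)
        Xs = apply_scaler(self.scaler_, X)
        svc = SVC(C=self.C, kernel="rbf", gamma=self.gamma_)
        svc.fit(Xs, y)
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted_input(self, X) -> np.ndarray:
        if not hasattr(self, "support_vectors_"):
            raise StateError("classifier used before fitting")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise FormatError(
                f"expected {self.n_features_in_} feature columns, "
                f"got shape {X.shape}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """h(x) = sum_i alpha_i y_i k(sv_i, x) + w0 in scaled space."""
        X = self._check_fitted_input(X)
        Xs = apply_scaler(self.scaler_, X)
        sq = cdist(Xs, self.support_vectors_, metric="sqeuclidean")
        K = np.exp(-self.gamma_ * sq)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        h = self.decision_function(X)
        return self.classes_[(h >= 0).astype(int)]

    # -- persistence -------------------------------------------------------

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        """JSON-serialisable snapshot; round-trips bit-exactly."""
        self._check_fitted_input(np.zeros((1, self.n_features_in_)))
        return {
            "format_version": 1,
            "kind": "rbf_svm",
            "C": self.C,
            "sigma": self.sigma,
            "gamma": self.gamma_,
            "feature_names": list(feature_names) if feature_names else None,
            "classes": self.classes_.tolist(),
            "scaler": {
                "data_min": self.scaler_.data_min.tolist(),
                "data_max": self.scaler_.data_max.tolist(),
            },
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpO2SVMClassifier":
        from .errors import SchemaError

        required = (
            "C", "sigma", "classes", "scaler", "support_vectors",
            "dual_coef", "intercept",
        )
        for key in required:
            if key not in d:
                raise SchemaError(f"model document missing field '{key}'")
        for key in ("data_min", "data_max"):
            if key not in d["scaler"]:
                raise SchemaError(f"model scaler missing field '{key}'")
        est = cls(C=d["C"], sigma=d["sigma"])
        est.classes_ = np.asarray(d["classes"])
        est.scaler_ = ScalerParams(
            data_min=np.asarray(d["scaler"]["data_min"], float),
            data_max=np.asarray(d["scaler"]["data_max"], float),
        )
        est.support_vectors_ = np.asarray(d["support_vectors"], float)
        est.dual_coef_ = np.asarray(d["dual_coef"], float)
        est.intercept_ = float(d["intercept"])
        est.n_features_in_ = est.support_vectors_.shape[1]
        return est


class AdaBoostBaseline(ClassifierMixin, BaseEstimator):
    """Boosted decision stumps through the same scaling convention.

    30 weak classifiers by default — the strongest operating point
    among stump ensembles of 10-40 for this feature set.
    """

    def __init__(self, n_estimators: int = 30, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = _check_two_classes(y)
        self.scaler_ = fit_scaler(X)
        self.ensemble_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )
        self.ensemble_.fit(apply_scaler(self.scaler_, X), y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "ensemble_"):
            raise StateError("classifier used before fitting")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise FormatError(f"expected {self.n_features_in_} columns")
        return self.ensemble_.predict(apply_scaler(self.scaler_, X))


# thin functional wrappers over the estimators


def train_svm(X, y, config: TrainingConfig | None = None) -> SpO2SVMClassifier:
    cfg = config or TrainingConfig()
    return SpO2SVMClassifier(C=cfg.C, sigma=cfg.sigma).fit(X, y)


def predict(model: SpO2SVMClassifier, X) -> np.ndarray:
    return model.predict(X)


def train_adaboost_baseline(
    X, y, n_estimators: int = 30, seed: int = 0
) -> AdaBoostBaseline:
    return AdaBoostBaseline(n_estimators=n_estimators, random_state=seed).fit(X, y)


# ---------------------------------------------------------------------------
# metrics and cross-validation


@dataclass
class ConfusionCounts:
    """2x2 confusion table with apnea as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )

    @classmethod
    def from_labels(
        cls, y_true, y_pred, positive=LABEL_APNEA
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive
        hit = y_pred == y_true
        return cls(
            tp=int(np.sum(pos & hit)),
            tn=int(np.sum(~pos & hit)),
            fp=int(np.sum(~pos & ~hit)),
            fn=int(np.sum(pos & ~hit)),
        )

    def to_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/(P+N). A zero denominator yields NaN (the
    undefined marker), never an exception.
    """
    sens = counts.tp / counts.p if counts.p > 0 else math.nan
    spec = counts.tn / counts.n if counts.n > 0 else math.nan
    total = counts.p + counts.n
    acc = (counts.tp + counts.tn) / total if total > 0 else math.nan
    return sens, spec, acc


def _num_or_none(x: float) -> float | None:
    return None if isinstance(x, float) and math.isnan(x) else x


@dataclass
class EvaluationReport:
    """Per-fold and pooled confusion counts with derived metrics.

    Metrics are stored as fractions; percent formatting belongs to the
    display layer only.
    """

    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    config: dict = field(default_factory=dict)
    seed: int = 0
    classifier: str = "rbf_svm"

    def to_dict(self) -> dict:
        folds = []
        for c in self.fold_counts:
            sens, spec, acc = compute_metrics(c)
            folds.append(
                {
                    **c.to_dict(),
                    "sensitivity": _num_or_none(sens),
                    "specificity": _num_or_none(spec),
                    "accuracy": _num_or_none(acc),
                }
            )
        return {
            "format_version": 1,
            "classifier": self.classifier,
            "config": self.config,
            "seed": self.seed,
            "folds": folds,
            "pooled": self.pooled.to_dict(),
            "sensitivity": _num_or_none(self.sensitivity),
            "specificity": _num_or_none(self.specificity),
            "accuracy": _num_or_none(self.accuracy),
        }


def cv_splits(y, folds: int, seed: int, groups=None):
    """Stratified (optionally grouped) fold indices; deterministic in seed."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise TrainingError(
            f"smallest class has {counts.min()} examples, fewer than "
            f"{folds} folds; use fewer folds"
        )
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros_like(y), y, groups=groups))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y), y))


def cross_validate(
    X,
    y,
    estimator: BaseEstimator | None = None,
    *,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    groups=None,
    return_models: bool = False,
):
    """Stratified k-fold evaluation with no train/test leakage.

    The estimator (its internal scaler included) is cloned and fitted on
    each training fold only; confusion counts come from the held-out
    fold. Pooled counts sum the folds into a single 2x2 table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    est = estimator if estimator is not None else SpO2SVMClassifier()
    splits = cv_splits(y, folds=folds, seed=seed, groups=groups)
    fold_counts: list[ConfusionCounts] = []
    models = []
    for train_idx, test_idx in splits:
        model = clone(est).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        fold_counts.append(ConfusionCounts.from_labels(y[test_idx], pred))
        if return_models:
            models.append(model)
    pooled = sum(fold_counts, ConfusionCounts())
    sens, spec, acc = compute_metrics(pooled)
    report = EvaluationReport(
        fold_counts=fold_counts,
        pooled=pooled,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        config={"folds": folds, **est.get_params()},
        seed=seed,
        classifier=type(est).__name__,
    )
    return (report, splits, models) if return_models else report
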