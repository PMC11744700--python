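"""Regression and classification of photophysics from POFP matrices.

The model zoo mirrors the standard benchmark set for small-data QSPR:
linear models, support-vector machines, k-nearest neighbours, decision
trees, random forests, gradient boosting, and a four-layer fully connected
neural network (three ReLU hidden layers + linear/softmax output, Adam,
batch 32, early stopping). Regression targets are transition energies in eV
(wavelengths are converted via E = 1240/lambda before fitting); reported
metrics are R^2, MAE and MSE for regression and accuracy, weighted-average
F1 and (row-normalizable) confusion matrices for classification, evaluated
by seeded 5-fold cross-validation (stratified for classification).

Fingerprint columns are standardized on the training fold only; the scaler
is stored with the model. The FCNN additionally exposes an analytic
input-gradient contract (d output / d input), the hook used by the
integrated-gradient attribution module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

INPUT_DIM = 46

FAMILIES = (
    "linear", "svr_or_svm", "knn", "decision_tree", "random_forest",
    "gradient_boosting", "fcnn",
)
TASKS = ("regression", "classification")

FCNN_DEFAULTS = dict(
    hidden_layer_sizes=(128, 64, 32),
    activation="relu",
    solver="adam",
    learning_rate_init=1e-3,
    batch_size=32,
    max_iter=500,
    early_stopping=True,
    validation_fraction=0.1,
    n_iter_no_change=25,
)


class UnsupportedGradientError(TypeError):
    """The model family does not expose the input-gradient contract."""


@dataclass(frozen=True)
class ModelSpec:
    """Which learner to build, for which task, and with what knobs."""

    family: str
    task: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    reg = spec.task == "regression"
    if spec.family == "linear":
        if reg:
            return LinearRegression(**hp)
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.family == "svr_or_svm":
        return SVR(**hp) if reg else SVC(random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsRegressor(**hp) if reg else KNeighborsClassifier(**hp)
    if spec.family == "decision_tree":
        cls = DecisionTreeRegressor if reg else DecisionTreeClassifier
        return cls(random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        return cls(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        cls = GradientBoostingRegressor if reg else GradientBoostingClassifier
        return cls(random_state=spec.seed, **hp)
    # fcnn
    params = {**FCNN_DEFAULTS, **hp}
    cls = MLPRegressor if reg else MLPClassifier
    return cls(random_state=spec.seed, **params)


class TrainedModel:
    """A (possibly still unfitted) learner plus its training-fold scaler."""

    def __init__(self, spec: ModelSpec, input_dim: int = INPUT_DIM):
        self.spec = spec
        self.input_dim = input_dim
        self.scaler = StandardScaler()
        self.estimator = _build_estimator(spec)
        self.fitted = False

    # -- prediction contract -------------------------------------------------

    def _check_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        return self.estimator.predict(self.scaler.transform(self._check_x(X)))

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (classification) or predictions (regression)."""
        if self.spec.task == "regression":
            return self.predict(X)
        Xs = self.scaler.transform(self._check_x(X))
        return self.estimator.predict_proba(Xs)

    # -- gradient contract ---------------------------------------------------

    def _mlp_forward(self, xs: np.ndarray):
        est = self.estimator
        pre, act = [], [xs]
        z = xs
        n = len(est.coefs_)
        for i, (W, b) in enumerate(zip(est.coefs_, est.intercepts_)):
            a = z @ W + b
            pre.append(a)
            z = np.maximum(a, 0.0) if i < n - 1 else a
            act.append(z)
        return pre, act

    def input_gradient(self, x: np.ndarray, target=None,
                       output: str = "probability") -> np.ndarray:
        """d(model output)/d(input) at a single raw-scale input vector.

        For regression the output is the predicted energy; for
        classification it is the softmax probability of ``target`` (a class
        label), or the corresponding logit when ``output='logit'``. The
        chain rule through the stored standardizer is included, so the
        returned gradient is on the raw fingerprint scale.
        """
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape[0] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features")
        xs = self.scaler.transform(x[None, :])[0]

        if self.spec.family == "linear" and self.spec.task == "regression":
            g_std = np.asarray(self.estimator.coef_, dtype=float).reshape(-1)
            return g_std / self.scaler.scale_
        if self.spec.family != "fcnn":
            raise UnsupportedGradientError(
                f"family {self.spec.family!r} has no gradient contract"
            )

        pre, act = self._mlp_forward(xs)
        out = pre[-1]
        if self.spec.task == "regression":
            g_out = np.ones_like(out)
        else:
            classes = list(self.estimator.classes_)
            if target is None:
                raise ValueError("classification gradient needs a target class")
            k = classes.index(target)
            if out.shape[0] == 1:  # binary net: single logit, logistic output
                p1 = 1.0 / (1.0 + np.exp(-out[0]))
                if output == "logit":
                    g_out = np.array([1.0 if k == 1 else -1.0])
                else:
                    g_out = np.array([p1 * (1 - p1) * (1.0 if k == 1 else -1.0)])
            else:
                if output == "logit":
                    g_out = np.eye(out.shape[0])[k]
                else:
                    z = out - out.max()
                    p = np.exp(z) / np.exp(z).sum()
                    g_out = p[k] * (np.eye(out.shape[0])[k] - p)
        g = g_out
        coefs = self.estimator.coefs_
        for i in range(len(coefs) - 1, 0, -1):
            g = (coefs[i] @ g) * (pre[i - 1] > 0)
        g = coefs[0] @ g
        return g / self.scaler.scale_

    @property
    def loss_curve_(self):
        return getattr(self.estimator, "loss_curve_", None)


def build_fcnn(input_dim: int = INPUT_DIM, task: str = "regression",
               hidden_sizes: Sequence[int] = (128, 64, 32),
               seed: int = 0) -> TrainedModel:
    """An unfitted four-layer FCNN scaffold (ReLU after each hidden layer)."""
    hidden_sizes = tuple(int(h) for h in hidden_sizes)
    if len(hidden_sizes) != 3 or any(h < 1 for h in hidden_sizes):
        raise ValueError("FCNN needs exactly 3 positive hidden sizes")
    spec = ModelSpec("fcnn", task,
                     {"hidden_layer_sizes": hidden_sizes}, seed=seed)
    return TrainedModel(spec, input_dim=input_dim)


def fit(model: TrainedModel | ModelSpec, X: np.ndarray,
        y: np.ndarray) -> TrainedModel:
    """Fit a scaffold (or a spec) on raw fingerprints and targets.

    The standardizer is fit on exactly the rows given here, so fold-wise
    calls never leak test statistics. Degenerate (zero-variance) targets are
    permitted.
    """
    if isinstance(model, ModelSpec):
        model = TrainedModel(model, input_dim=np.asarray(X).shape[1])
    X = model._check_x(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    y = np.asarray(y)
    Xs = model.scaler.fit_transform(X)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        model.estimator.fit(Xs, y)
    model.fitted = True
    return model


@dataclass(frozen=True)
class RegressionMetrics:
    r2: float
    mae: float
    mse: float
    degenerate_targets: bool = False

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "mse": self.mse}


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    weighted_f1: float
    confusion: np.ndarray
    labels: tuple

    @property
    def confusion_normalized(self) -> np.ndarray:
        """Row-normalized confusion matrix (rows with support sum to 1)."""
        row = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.confusion / row
        return np.where(row > 0, out, 0.0)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "weighted_f1": self.weighted_f1}


def evaluate_regression(y_true, y_pred) -> RegressionMetrics:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    degenerate = bool(np.var(y_true) == 0)
    if degenerate:
        warnings.warn("zero-variance targets: R^2 is ill-defined")
    return RegressionMetrics(
        r2=float(r2_score(y_true, y_pred)) if not degenerate else float("nan"),
        mae=float(mean_absolute_error(y_true, y_pred)),
        mse=float(mean_squared_error(y_true, y_pred)),
        degenerate_targets=degenerate,
    )


def evaluate_classification(y_true, y_pred,
                            labels: Optional[Sequence] = None) -> ClassificationMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    return ClassificationMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        weighted_f1=float(f1_score(y_true, y_pred, labels=labels,
                                   average="weighted", zero_division=0)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        labels=tuple(labels),
    )


def cross_validate(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                   folds: int = 5, seed: int = 0) -> dict:
    """Seeded k-fold cross-validation (stratified for classification).

    Returns ``{"per_fold": [metrics...], "mean": {...}}``. A class rarer
    than the fold count relaxes stratification with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    if spec.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < folds:
            warnings.warn(
                "a class has fewer members than folds; stratification relaxed"
            )
            splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        else:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                       random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)

    per_fold = []
    for train_idx, test_idx in splitter.split(X, y):
        model = fit(spec, X[train_idx], y[train_idx])
        y_pred = model.predict(X[test_idx])
        if spec.task == "regression":
            per_fold.append(evaluate_regression(y[test_idx], y_pred))
        else:
            per_fold.append(evaluate_classification(
                y[test_idx], y_pred, labels=sorted(set(y))))
    keys = per_fold[0].to_dict().keys()
    mean = {k: float(np.mean([m.to_dict()[k] for m in per_fold])) for k in keys}
    return {"per_fold": per_fold, "mean": mean}
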