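"""One-against-all multiclass kernel SVM, repeated-holdout evaluation, and
the bucket-of-models ensemble.

One binary machine is trained per class (class vs rest); the predicted class
is the machine with the largest decision value, ties resolved toward the
lowest class index.  Five kernels are supported: linear, quadratic
(polynomial degree 2), polynomial (degree 3), RBF, and the "MLP" sigmoid
kernel tanh(scale * <x, x'> + offset).  Evaluation follows a repeated
stratified 80/20 holdout protocol, with MSE computed from one-hot-coded
predictions against the one-hot targets so that ANN and SVM results share a
metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

KERNEL_NAMES = ("linear", "quadratic", "polynomial", "rbf", "mlp")


class KernelError(ValueError):
    """Unknown or inconsistent kernel specification."""


class SVMDataError(ValueError):
    """Training data unusable for the requested machine."""


@dataclass
class KernelSpec:
    """Named kernel with its constants.

    ``gamma`` follows sklearn's conventions ("scale" adapts to feature
    variance); the sigmoid ("mlp") kernel uses ``mlp_scale`` (default 1/d,
    i.e. "auto") and ``mlp_offset`` -1.
    """

    name: str = "polynomial"
    degree: int = 3
    gamma: float | str = "scale"
    C: float = 1.0
    mlp_scale: float | str = "auto"
    mlp_offset: float = -1.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise KernelError(
                f"unknown kernel {self.name!r}; choose one of {KERNEL_NAMES}")
        if self.name == "polynomial" and self.degree < 2:
            raise KernelError("polynomial kernel needs degree >= 2")
        if self.name == "rbf" and not (self.gamma in ("scale", "auto")
                                       or float(self.gamma) > 0):
            raise KernelError("rbf kernel needs gamma > 0")

    def sklearn_params(self) -> dict:
        if self.name == "linear":
            return {"kernel": "linear", "C": self.C}
        if self.name == "quadratic":
            return {"kernel": "poly", "degree": 2, "gamma": self.gamma,
                    "coef0": 1.0, "C": self.C}
        if self.name == "polynomial":
            return {"kernel": "poly", "degree": self.degree, "gamma": self.gamma,
                    "coef0": 1.0, "C": self.C}
        if self.name == "rbf":
            return {"kernel": "rbf", "gamma": self.gamma, "C": self.C}
        return {"kernel": "sigmoid", "gamma": self.mlp_scale,
                "coef0": self.mlp_offset, "C": self.C}


class OneVsAllSVC(BaseEstimator, ClassifierMixin):
    """One-against-all SVM: one binary machine per class, argmax decision.

    Attributes (after fit): ``classes_``, ``machines_`` (one fitted binary
    SVC per class, in class order).
    """

    def __init__(self, kernel="polynomial", degree=3, gamma="scale", C=1.0,
                 mlp_scale="auto", mlp_offset=-1.0, random_state=None):
        self.kernel = kernel
        self.degree = degree
        self.gamma = gamma
        self.C = C
        self.mlp_scale = mlp_scale
        self.mlp_offset = mlp_offset
        self.random_state = random_state

    def _spec(self) -> KernelSpec:
        return KernelSpec(name=self.kernel, degree=self.degree, gamma=self.gamma,
                          C=self.C, mlp_scale=self.mlp_scale,
                          mlp_offset=self.mlp_offset)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise SVMDataError("features contain non-finite values")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise SVMDataError("need at least two classes to train")
        params = self._spec().sklearn_params()
        self.machines_ = []
        base = SVC(random_state=self.random_state, **params)
        for cls in self.classes_:
            machine = clone(base)
            machine.fit(X, (y == cls).astype(int))
            self.machines_.append(machine)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "machines_")
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.decision_function(X) for m in self.machines_])

    def predict(self, X):
        # first maximum -> lowest class index on decision-value ties
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train_ova_svm(X, y, kernel: KernelSpec | str = "polynomial", seed=None,
                  expected_classes=None) -> OneVsAllSVC:
    """Train a one-against-all SVM, checking every expected class is present."""
    spec = KernelSpec(name=kernel) if isinstance(kernel, str) else kernel
    y = np.asarray(y)
    if expected_classes is not None:
        missing = sorted(set(expected_classes) - set(np.unique(y).tolist()))
        if missing:
            raise SVMDataError(f"classes absent from training data: {missing}")
    model = OneVsAllSVC(kernel=spec.name, degree=spec.degree, gamma=spec.gamma,
                        C=spec.C, mlp_scale=spec.mlp_scale,
                        mlp_offset=spec.mlp_offset, random_state=seed)
    return model.fit(X, y)


def _one_hot_mse(pred, true, classes) -> float:
    """MSE between one-hot-coded predictions and one-hot targets."""
    classes = np.asarray(classes)
    p = np.searchsorted(classes, pred)
    t = np.searchsorted(classes, true)
    P = np.zeros((len(p), len(classes)))
    P[np.arange(len(p)), p] = 1.0
    T = np.zeros_like(P)
    T[np.arange(len(t)), t] = 1.0
    return float(np.mean((P - T) ** 2))


def repeated_holdout_evaluate(X, y, kernel="polynomial", n_rounds=20,
                              train_frac=0.8, seed=0, model_factory=None) -> dict:
    """Repeated seeded stratified holdout (default 20 rounds of 80/20).

    Returns mean accuracy (percent), mean one-hot MSE, and the per-round
    values.  ``model_factory`` may supply any classifier constructor taking a
    ``random_state``; by default a one-against-all SVM with ``kernel``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if np.min(np.bincount(np.searchsorted(classes, y))) < 2:
        raise SVMDataError("every class needs >= 2 samples for a stratified holdout")
    if model_factory is None:
        spec = KernelSpec(name=kernel) if isinstance(kernel, str) else kernel

        def model_factory(rs):
            return OneVsAllSVC(kernel=spec.name, degree=spec.degree,
                               gamma=spec.gamma, C=spec.C,
                               mlp_scale=spec.mlp_scale,
                               mlp_offset=spec.mlp_offset, random_state=rs)
    splitter = StratifiedShuffleSplit(n_splits=n_rounds, train_size=train_frac,
                                      random_state=seed)
    accs, mses = [], []
    for round_i, (tr, te) in enumerate(splitter.split(X, y)):
        model = model_factory(seed + round_i)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        accs.append(100.0 * float(np.mean(pred == y[te])))
        mses.append(_one_hot_mse(pred, y[te], classes))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "mean_mse": float(np.mean(mses)),
        "round_accuracies": accs,
        "round_mses": mses,
    }


def kernel_comparison(X, y, kernels=KERNEL_NAMES, n_rounds=20, train_frac=0.8,
                      seed=0) -> pd.DataFrame:
    """Five-row kernel comparison grid: mean accuracy and MSE per kernel."""
    rows = []
    for name in kernels:
        res = repeated_holdout_evaluate(X, y, kernel=name, n_rounds=n_rounds,
                                        train_frac=train_frac, seed=seed)
        rows.append({"kernel": name, "mse": res["mean_mse"],
                     "accuracy": res["mean_accuracy"]})
    return pd.DataFrame(rows)


@dataclass
class BucketResult:
    """Best model in the bucket plus every member's evaluation accuracy."""

    best_model: OneVsAllSVC
    best_index: int
    accuracies: list[float] = field(default_factory=list)


class BucketOfModelsSVC(BaseEstimator, ClassifierMixin):
    """Bucket-of-models ensemble: train ``n_models`` seeded machines on
    re-split data and keep the single best by holdout accuracy."""

    def __init__(self, kernel="polynomial", degree=3, gamma="scale", C=1.0,
                 n_models=50, train_frac=0.8, random_state=None):
        self.kernel = kernel
        self.degree = degree
        self.gamma = gamma
        self.C = C
        self.n_models = n_models
        self.train_frac = train_frac
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        splitter = StratifiedShuffleSplit(n_splits=self.n_models,
                                          train_size=self.train_frac,
                                          random_state=self.random_state)
        best_acc, best_model, best_i, accs = -1.0, None, -1, []
        for i, (tr, te) in enumerate(splitter.split(X, y)):
            model = OneVsAllSVC(kernel=self.kernel, degree=self.degree,
                                gamma=self.gamma, C=self.C,
                                random_state=self.random_state)
            model.fit(X[tr], y[tr])
            acc = float(np.mean(model.predict(X[te]) == y[te]))
            accs.append(acc)
            if acc > best_acc:  # strict: first best wins ties deterministically
                best_acc, best_model, best_i = acc, model, i
        self.best_model_ = best_model
        self.best_index_ = best_i
        self.member_accuracies_ = accs
        self.classes_ = best_model.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "best_model_")
        return self.best_model_.predict(X)


def bucket_of_models(X, y, kernel="polynomial", n_models=50, seed=0,
                     train_frac=0.8) -> BucketResult:
    """Functional wrapper over :class:`BucketOfModelsSVC`."""
    spec = KernelSpec(name=kernel) if isinstance(kernel, str) else kernel
    bucket = BucketOfModelsSVC(kernel=spec.name, degree=spec.degree,
                               gamma=spec.gamma, C=spec.C, n_models=n_models,
                               train_frac=train_frac, random_state=seed)
    bucket.fit(X, y)
    return BucketResult(best_model=bucket.best_model_,
                        best_index=bucket.best_index_,
                        accuracies=bucket.member_accuracies_)
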