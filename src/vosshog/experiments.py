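"""Experiment protocols tying descriptors, classifiers, and evaluation
together: the classifier x descriptor grid, and the ensemble-versus-single
comparison repeated over seeds."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ann import BaggedMLPEnsemble, split_indices, train_mlp_scg
from .descriptors import HOGTransformer, LBPTransformer
from .encoding import CLASS_NAMES
from .evaluation import ExperimentReport, confusion_matrix, mse_metric, summarize_grid
from .svm import BucketOfModelsSVC, OneVsAllSVC, _one_hot_mse
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split


def featurize(samples, descriptor: str = "hog") -> np.ndarray:
    """Descriptor feature matrix for sequences or Voss matrices."""
    if descriptor == "hog":
        return HOGTransformer().fit_transform(samples)
    if descriptor == "lbp":
        return LBPTransformer().fit_transform(samples)
    raise ValueError(f"unknown descriptor {descriptor!r} (hog or lbp)")


def _one_hot(labels, classes):
    codes = np.searchsorted(classes, labels)
    T = np.zeros((len(codes), len(classes)))
    T[np.arange(len(codes)), codes] = 1.0
    return T


def _report(combo, y_true, y_pred, mse, seed, config, evaluation_set="test"):
    observed = set(y_true) | set(y_pred)
    order = CLASS_NAMES if observed <= set(CLASS_NAMES) else sorted(observed)
    cm = confusion_matrix(y_true, y_pred, class_order=order)
    return ExperimentReport(combo=combo, confusion=cm, mse=mse, seeds=[seed],
                            config=config, evaluation_set=evaluation_set)


def run_combo(X, y, model_kind: str, descriptor: str, seed: int = 0, *,
              hidden_size=30, max_epochs=200, n_base=15, n_selected=5,
              n_rounds=20, n_models=15, train_frac=0.8) -> ExperimentReport:
    """Train and evaluate one classifier family on one descriptor's features.

    ``model_kind`` is one of ``ann``, ``ann-ensemble``, ``svm``,
    ``svm-ensemble``; held-out evaluation follows each family's protocol
    (70/15/15 with early stopping for the networks, stratified 80/20
    holdouts for the SVMs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    combo = f"{model_kind}/{descriptor}"
    config = {"hidden_size": hidden_size, "max_epochs": max_epochs,
              "n_base": n_base, "n_selected": n_selected,
              "n_rounds": n_rounds, "n_models": n_models}

    if model_kind == "ann":
        res = train_mlp_scg(X, y, hidden_size=hidden_size,
                            max_epochs=max_epochs, seed=seed)
        te = res.indices[2]
        pred = res.model.predict(X[te])
        return _report(combo, y[te], pred, res.test_mse, seed, config)

    if model_kind == "ann-ensemble":
        tr, val, te = split_indices(y, (0.70, 0.15, 0.15), seed=seed)
        fit_idx = np.concatenate([tr, val])
        ens = BaggedMLPEnsemble(n_base=n_base, n_selected=n_selected,
                                hidden_size=hidden_size, max_epochs=max_epochs,
                                random_state=seed)
        ens.fit(X[fit_idx], y[fit_idx])
        pred = ens.predict(X[te])
        mse = _one_hot_mse(pred, y[te], ens.classes_)
        return _report(combo, y[te], pred, mse, seed, config)

    if model_kind == "svm":
        splitter = StratifiedShuffleSplit(n_splits=n_rounds,
                                          train_size=train_frac,
                                          random_state=seed)
        trues, preds, mses = [], [], []
        for tr, te in splitter.split(X, y):
            model = OneVsAllSVC(random_state=seed).fit(X[tr], y[tr])
            p = model.predict(X[te])
            trues.append(y[te])
            preds.append(p)
            mses.append(_one_hot_mse(p, y[te], model.classes_))
        y_true = np.concatenate(trues)
        y_pred = np.concatenate(preds)
        return _report(combo, y_true, y_pred, float(np.mean(mses)), seed,
                       config, evaluation_set=f"{n_rounds}x holdout")

    if model_kind == "svm-ensemble":
        tr, te = train_test_split(np.arange(len(y)), train_size=train_frac,
                                  random_state=seed % 2**32, stratify=y)
        bucket = BucketOfModelsSVC(n_models=n_models, random_state=seed)
        bucket.fit(X[tr], y[tr])
        pred = bucket.predict(X[te])
        mse = _one_hot_mse(pred, y[te], bucket.classes_)
        return _report(combo, y[te], pred, mse, seed, config)

    raise ValueError(f"unknown model kind {model_kind!r}")


def run_experiment_grid(features_by_descriptor: dict, y, seed: int = 0,
                        **sizes) -> tuple[list, pd.DataFrame]:
    """All classifier x descriptor combinations and their summary grid."""
    reports = []
    for descriptor, X in features_by_descriptor.items():
        for model_kind in ("ann", "ann-ensemble", "svm", "svm-ensemble"):
            reports.append(run_combo(X, y, model_kind, descriptor, seed=seed,
                                     **sizes))
    return reports, summarize_grid(reports)


def ensemble_vs_single_study(X, y, seeds, *, hidden_size=30, max_epochs=200,
                             n_base=15, n_selected=5,
                             n_single=5) -> pd.DataFrame:
    """Per seed: held-out accuracy of the bagging ensemble versus the median
    of independently trained single networks on the same split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rows = []
    for seed in seeds:
        tr, val, te = split_indices(y, (0.70, 0.15, 0.15), seed=seed)
        fit_idx = np.concatenate([tr, val])
        singles = []
        for j in range(n_single):
            res = train_mlp_scg(X[fit_idx], y[fit_idx],
                                hidden_size=hidden_size,
                                max_epochs=max_epochs,
                                fractions=(0.824, 0.088, 0.088),
                                seed=seed * 1000 + j)
            singles.append(100.0 * float(np.mean(
                res.model.predict(X[te]) == y[te])))
        ens = BaggedMLPEnsemble(n_base=n_base, n_selected=n_selected,
                                hidden_size=hidden_size,
                                max_epochs=max_epochs, random_state=seed)
        ens.fit(X[fit_idx], y[fit_idx])
        ens_acc = 100.0 * float(np.mean(ens.predict(X[te]) == y[te]))
        rows.append({"seed": seed, "ensemble_accuracy": ens_acc,
                     "median_single_accuracy": float(np.median(singles)),
                     "ensemble_wins": ens_acc >= float(np.median(singles))})
    return pd.DataFrame(rows)
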