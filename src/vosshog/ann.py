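"""Multilayer perceptron with scaled-conjugate-gradient training and bagging.

The network is the descriptor classifier of the pipeline: an input layer the
width of the feature vector (81 for HOG, 256 for LBP), two equal-width tanh
hidden layers, and six tanh output units trained against one-hot {0,1} target
vectors with a mean-squared-error objective.  Training uses Moller's scaled
conjugate gradient (SCG), a line-search-free conjugate-gradient method, with
early stopping at the minimum validation MSE.  The bagging ensemble trains
``n_base`` networks on bootstrap resamples, keeps the best-performing members
(out-of-bag accuracy), and predicts by plurality vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


class DataSplitError(ValueError):
    """Dataset unusable for the requested split or training."""


class VoteError(ValueError):
    """Invalid ensemble vote input."""


# ---------------------------------------------------------------------------
# Neuron / network forward primitives


def neuron_forward(x, weights, bias, activation=np.tanh) -> float:
    """Single artificial neuron: f(w0 + sum_i w_i x_i)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"input length {x.shape} != weight length {w.shape}")
    return float(activation(bias + x @ w))


def _forward(X: np.ndarray, layers: list[tuple[np.ndarray, np.ndarray]]):
    """Forward pass through tanh layers; returns all activations."""
    activations = [X]
    a = X
    for W, b in layers:
        a = np.tanh(a @ W + b)
        activations.append(a)
    return activations


def _mse(outputs: np.ndarray, targets: np.ndarray) -> float:
    return float(np.mean((outputs - targets) ** 2))


# ---------------------------------------------------------------------------
# Flat parameter vector <-> layer list


def _shapes(sizes: list[int]):
    return [((sizes[i], sizes[i + 1]), (sizes[i + 1],)) for i in range(len(sizes) - 1)]


def _unpack(theta: np.ndarray, sizes: list[int]):
    layers, pos = [], 0
    for (ws, bs) in _shapes(sizes):
        n_w = ws[0] * ws[1]
        W = theta[pos : pos + n_w].reshape(ws)
        pos += n_w
        b = theta[pos : pos + bs[0]]
        pos += bs[0]
        layers.append((W, b))
    return layers


def _pack(layers) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in layers])


def _loss_and_grad(theta, sizes, X, T):
    """MSE over samples and output units, with its gradient by backprop."""
    layers = _unpack(theta, sizes)
    acts = _forward(X, layers)
    out = acts[-1]
    diff = out - T
    loss = float(np.mean(diff**2))
    scale = 2.0 / diff.size
    delta = scale * diff * (1.0 - out**2)
    grads = []
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        a_prev = acts[li]
        gW = a_prev.T @ delta
        gb = delta.sum(axis=0)
        grads.append((gW, gb))
        if li > 0:
            delta = (delta @ W.T) * (1.0 - acts[li] ** 2)
    grads.reverse()
    return loss, _pack(grads)


# ---------------------------------------------------------------------------
# Scaled conjugate gradient (Moller 1993)


def _scg_minimize(theta0, fun_grad, max_updates, callback, sigma0=5e-5,
                  lambda0=5e-7, grad_tol=1e-8, max_failures=50):
    """Minimize fun_grad (returning (loss, grad)) with SCG.

    ``callback(theta)`` runs after every successful weight update and may
    return True to stop.  Each update counts as one training epoch.
    """
    theta = theta0.copy()
    n = theta.size
    loss, grad = fun_grad(theta)
    r = -grad
    p = r.copy()
    success = True
    lam, lam_bar = lambda0, 0.0
    updates = 0
    failures = 0
    delta = 1.0
    while updates < max_updates:
        norm_p2 = float(p @ p)
        if norm_p2 == 0.0 or np.sqrt(float(r @ r)) < grad_tol:
            break
        if success:
            sigma = sigma0 / np.sqrt(norm_p2)
            _, grad_sigma = fun_grad(theta + sigma * p)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * norm_p2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / norm_p2)
            delta = -delta + lam * norm_p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new, grad_new = fun_grad(theta + alpha * p)
        comparison = 2.0 * delta * (loss - loss_new) / mu**2
        if comparison >= 0:
            theta = theta + alpha * p
            loss, grad = loss_new, grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            failures = 0
            updates += 1
            if updates % n == 0:  # restart the conjugate directions
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-20)
            if callback(theta):
                break
            if not np.isfinite(loss):
                raise FloatingPointError("SCG training diverged (non-finite loss)")
        else:
            lam_bar = lam
            success = False
            failures += 1
            if failures >= max_failures:
                break
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / norm_p2
    return theta


# ---------------------------------------------------------------------------
# Dataset utilities


def split_indices(y, fractions=(0.70, 0.15, 0.15), seed=0, stratify=True):
    """Seeded disjoint/exhaustive split into index arrays, stratified by class.

    Global split sizes follow the fractions exactly (largest-remainder
    rounding); per-class allocations are rounded subject to those totals.
    Classes with fewer samples than splits degrade stratification (warned).
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or not np.isclose(fractions.sum(), 1.0):
        raise DataSplitError("split fractions must be positive and sum to 1")
    y = np.asarray(y)
    n = len(y)
    if n < len(fractions):
        raise DataSplitError(f"cannot split {n} samples into {len(fractions)} parts")
    rng = np.random.default_rng(seed)
    n_splits = len(fractions)

    # exact global sizes by largest remainder
    quotas = n * fractions
    sizes = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - sizes))[: n - sizes.sum()]:
        sizes[i] += 1

    classes, y_codes = np.unique(y, return_inverse=True)
    counts = np.bincount(y_codes)
    if stratify and np.any(counts < n_splits):
        small = classes[counts < n_splits]
        warnings.warn(
            f"classes {list(small)} have fewer samples than splits; "
            "stratification is degraded for them"
        )

    # per-class cell allocation: floor, then largest fractional parts subject
    # to row (class) and column (split) totals
    cell = np.zeros((len(classes), n_splits), dtype=int)
    frac_part = np.zeros_like(cell, dtype=float)
    if stratify:
        for c, n_c in enumerate(counts):
            q = n_c * fractions
            cell[c] = np.floor(q).astype(int)
            frac_part[c] = q - cell[c]
        col_left = sizes - cell.sum(axis=0)
        row_left = counts - cell.sum(axis=1)
        order = np.dstack(np.unravel_index(np.argsort(-frac_part, axis=None),
                                           frac_part.shape))[0]
        for c, s in order:
            if row_left[c] > 0 and col_left[s] > 0:
                cell[c, s] += 1
                row_left[c] -= 1
                col_left[s] -= 1
        for c in np.nonzero(row_left)[0]:  # spill where columns still open
            for s in np.nonzero(col_left)[0]:
                take = min(row_left[c], col_left[s])
                cell[c, s] += take
                row_left[c] -= take
                col_left[s] -= take
                if row_left[c] == 0:
                    break
        parts = [[] for _ in range(n_splits)]
        for c in range(len(classes)):
            idx = rng.permutation(np.nonzero(y_codes == c)[0])
            pos = 0
            for s in range(n_splits):
                parts[s].append(idx[pos : pos + cell[c, s]])
                pos += cell[c, s]
        out = tuple(rng.permutation(np.concatenate(p)) for p in parts)
    else:
        idx = rng.permutation(n)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        out = tuple(idx[bounds[i] : bounds[i + 1]] for i in range(n_splits))
    return out


def split_dataset(X, y, fractions=(0.70, 0.15, 0.15), seed=0, stratify=True):
    """Split features/labels into (train, validation, test) (X, y) pairs."""
    X = np.asarray(X)
    y = np.asarray(y)
    parts = split_indices(y, fractions, seed=seed, stratify=stratify)
    return tuple((X[idx], y[idx]) for idx in parts)


def bootstrap_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, n, size=n)


def bootstrap_resample(X, y=None, seed=0):
    """Equal-size resample with replacement (the bootstrap)."""
    X = np.asarray(X)
    if len(X) == 0:
        raise DataSplitError("cannot bootstrap an empty dataset")
    idx = bootstrap_indices(len(X), np.random.default_rng(seed))
    if y is None:
        return X[idx]
    y = np.asarray(y)
    return X[idx], y[idx]


def plurality_vote(predictions, class_order=None):
    """Winner by vote count; ties go to the earliest class in class_order."""
    predictions = list(predictions)
    if not predictions:
        raise VoteError("plurality vote over zero predictions")
    order = list(class_order) if class_order is not None else list(np.unique(predictions))
    counts = {c: 0 for c in order}
    for p in predictions:
        if p not in counts:
            raise VoteError(f"vote {p!r} outside the class order")
        counts[p] += 1
    return max(order, key=lambda c: (counts[c], -order.index(c)))


# ---------------------------------------------------------------------------
# Estimators


class ScgMLPClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer tanh MLP trained with scaled conjugate gradient.

    Both hidden layers share ``hidden_size`` units.  Targets are one-hot
    {0,1} vectors decoded by argmax; with tanh outputs both levels are
    reachable.  With ``early_stopping`` the returned weights are those of the
    epoch with minimum validation MSE (a validation set may be passed to
    ``fit`` explicitly, otherwise ``validation_fraction`` is carved from the
    training data).  Features are z-scored on the training data by default.

    Attributes (after fit): ``classes_``, ``layers_`` (list of (W, b)),
    ``loss_curve_`` / ``validation_curve_`` (per-epoch MSE, epoch 0 = initial
    weights), ``best_epoch_``, ``n_features_in_``.
    """

    def __init__(self, hidden_size=80, max_epochs=500, early_stopping=True,
                 validation_fraction=0.15, standardize=True, tol=1e-8,
                 random_state=None):
        self.hidden_size = hidden_size
        self.max_epochs = max_epochs
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.tol = tol
        self.random_state = random_state

    def _init_theta(self, sizes, rng):
        layers = []
        for (ws, bs) in _shapes(sizes):
            limit = 1.0 / np.sqrt(ws[0])
            layers.append((rng.uniform(-limit, limit, ws), np.zeros(bs[0])))
        return _pack(layers)

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise DataSplitError("training data contains a single class")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            X_val, y_val = validation_data
            X_val = np.asarray(X_val, dtype=float)
            y_val_codes = np.searchsorted(self.classes_, np.asarray(y_val))
            X_tr, codes_tr = X, y_codes
        elif self.early_stopping:
            frac = self.validation_fraction
            tr_idx, val_idx = split_indices(
                y_codes, (1.0 - frac, frac), seed=rng.integers(2**31 - 1))
            X_tr, codes_tr = X[tr_idx], y_codes[tr_idx]
            X_val, y_val_codes = X[val_idx], y_codes[val_idx]
        else:
            X_tr, codes_tr = X, y_codes
            X_val = None

        if self.standardize:
            self.mean_ = X_tr.mean(axis=0)
            scale = X_tr.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs_tr = (X_tr - self.mean_) / self.scale_

        n_out = len(self.classes_)
        T_tr = np.zeros((len(codes_tr), n_out))
        T_tr[np.arange(len(codes_tr)), codes_tr] = 1.0
        sizes = [X.shape[1], self.hidden_size, self.hidden_size, n_out]
        self._sizes = sizes
        theta0 = self._init_theta(sizes, rng)

        if X_val is not None and len(X_val):
            Xs_val = (X_val - self.mean_) / self.scale_
            T_val = np.zeros((len(y_val_codes), n_out))
            T_val[np.arange(len(y_val_codes)), y_val_codes] = 1.0
        else:
            Xs_val = T_val = None

        train_curve: list[float] = []
        val_curve: list[float] = []
        best = {"val": np.inf, "theta": theta0.copy(), "epoch": 0}

        def record(theta):
            loss = _mse(_forward(Xs_tr, _unpack(theta, sizes))[-1], T_tr)
            train_curve.append(loss)
            if Xs_val is not None:
                v = _mse(_forward(Xs_val, _unpack(theta, sizes))[-1], T_val)
                val_curve.append(v)
                if v < best["val"]:
                    best.update(val=v, theta=theta.copy(), epoch=len(val_curve) - 1)
            else:
                if loss < best["val"]:
                    best.update(val=loss, theta=theta.copy(), epoch=len(train_curve) - 1)
            return False

        record(theta0)
        _scg_minimize(theta0, lambda t: _loss_and_grad(t, sizes, Xs_tr, T_tr),
                      self.max_epochs, record, grad_tol=self.tol)
        self.theta_ = best["theta"]
        self.layers_ = _unpack(self.theta_, sizes)
        self.best_epoch_ = best["epoch"]
        self.loss_curve_ = np.asarray(train_curve)
        self.validation_curve_ = np.asarray(val_curve) if val_curve else None
        return self

    def decision_function(self, X):
        """Raw tanh output vectors (one column per class)."""
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} != trained width {self.n_features_in_}"
            )
        Xs = (X - self.mean_) / self.scale_
        return _forward(Xs, self.layers_)[-1]

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def mlp_forward(x, model: ScgMLPClassifier) -> np.ndarray:
    """Output vector of a trained network for a single feature vector."""
    return model.decision_function(np.asarray(x, dtype=float)[None, :])[0]


@dataclass
class SCGTrainResult:
    """Trained network plus its per-epoch history and the data split."""

    model: ScgMLPClassifier
    history: pd.DataFrame
    indices: tuple  # (train, validation, test) index arrays
    test_accuracy: float
    test_mse: float


def train_mlp_scg(X, y, hidden_size=80, max_epochs=500,
                  fractions=(0.70, 0.15, 0.15), seed=0, **kwargs) -> SCGTrainResult:
    """70/15/15 split, SCG training with early stopping, held-out evaluation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tr, val, te = split_indices(y, fractions, seed=seed)
    for name, idx in (("training", tr), ("validation", val), ("test", te)):
        if len(idx) == 0:
            raise DataSplitError(f"{name} split is empty")
    model = ScgMLPClassifier(hidden_size=hidden_size, max_epochs=max_epochs,
                             random_state=seed, **kwargs)
    model.fit(X[tr], y[tr], validation_data=(X[val], y[val]))
    history = pd.DataFrame({
        "epoch": np.arange(len(model.loss_curve_)),
        "train_mse": model.loss_curve_,
        "validation_mse": model.validation_curve_,
    })
    out = model.decision_function(X[te])
    pred = model.classes_[np.argmax(out, axis=1)]
    T = np.zeros_like(out)
    T[np.arange(len(te)), np.searchsorted(model.classes_, y[te])] = 1.0
    return SCGTrainResult(
        model=model, history=history, indices=(tr, val, te),
        test_accuracy=100.0 * float(np.mean(pred == y[te])),
        test_mse=_mse(out, T),
    )


def hidden_size_sweep(X, y, sizes=range(10, 101, 10), seed=0, max_epochs=500,
                      **kwargs) -> pd.DataFrame:
    """Train one network per hidden width; report MSE/accuracy on both the
    full data and the held-out test split, labeling each explicitly."""
    rows = []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    for h in sizes:
        res = train_mlp_scg(X, y, hidden_size=h, max_epochs=max_epochs,
                            seed=seed, **kwargs)
        out_all = res.model.decision_function(X)
        pred_all = res.model.classes_[np.argmax(out_all, axis=1)]
        T_all = np.zeros_like(out_all)
        T_all[np.arange(len(y)), np.searchsorted(res.model.classes_, y)] = 1.0
        rows.append({
            "hidden_size": h,
            "mse_all": _mse(out_all, T_all),
            "accuracy_all": 100.0 * float(np.mean(pred_all == y)),
            "mse_test": res.test_mse,
            "accuracy_test": res.test_accuracy,
            "best_epoch": res.model.best_epoch_,
        })
    return pd.DataFrame(rows)


class BaggedMLPEnsemble(BaseEstimator, ClassifierMixin):
    """Bagging ensemble of SCG-trained MLPs with plurality voting.

    ``n_base`` networks are trained on independent bootstrap resamples; the
    members whose out-of-bag accuracy clears ``selection_threshold`` are kept
    (topped up / cut down to exactly ``n_selected`` by accuracy rank).
    Prediction is a per-sample plurality vote, ties resolved toward the
    lowest class index; the vote is invariant to member ordering.
    """

    def __init__(self, n_base=50, n_selected=12, selection_threshold=0.9475,
                 hidden_size=80, max_epochs=500, validation_fraction=0.15,
                 standardize=True, random_state=None):
        self.n_base = n_base
        self.n_selected = n_selected
        self.selection_threshold = selection_threshold
        self.hidden_size = hidden_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_selected > self.n_base:
            raise ValueError(
                f"n_selected={self.n_selected} exceeds n_base={self.n_base}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        members, accs = [], []
        n = len(X)
        for _ in range(self.n_base):
            seed = int(rng.integers(2**31 - 1))
            boot = bootstrap_indices(n, np.random.default_rng(seed))
            oob = np.setdiff1d(np.arange(n), boot)
            member = ScgMLPClassifier(
                hidden_size=self.hidden_size, max_epochs=self.max_epochs,
                validation_fraction=self.validation_fraction,
                standardize=self.standardize, random_state=seed)
            if len(oob) and len(np.unique(y[boot])) > 1:
                # out-of-bag samples double as the member's early-stopping
                # validation set and its selection benchmark
                member.fit(X[boot], y[boot], validation_data=(X[oob], y[oob]))
                acc = float(np.mean(member.predict(X[oob]) == y[oob]))
            else:
                member.fit(X[boot], y[boot])
                warnings.warn("bootstrap left no out-of-bag samples; "
                              "selecting on training accuracy")
                acc = float(np.mean(member.predict(X[boot]) == y[boot]))
            members.append(member)
            accs.append(acc)
        accs = np.asarray(accs)
        qualified = np.nonzero(accs >= self.selection_threshold)[0]
        pool = qualified if len(qualified) >= self.n_selected else np.arange(self.n_base)
        order = pool[np.argsort(-accs[pool], kind="stable")]
        self.selected_indices_ = np.sort(order[: self.n_selected])
        self.members_ = [members[i] for i in self.selected_indices_]
        self.member_accuracies_ = accs
        return self

    def _vote_counts(self, X):
        counts = np.zeros((len(np.atleast_2d(X)), len(self.classes_)))
        for member in self.members_:
            pred = member.predict(X)
            codes = np.searchsorted(self.classes_, pred)
            counts[np.arange(len(codes)), codes] += 1
        return counts

    def predict(self, X):
        check_is_fitted(self, "members_")
        # argmax returns the first maximum: the lowest class index wins ties
        return self.classes_[np.argmax(self._vote_counts(X), axis=1)]


def build_bagging_ensemble(X, y, n_base=50, n_selected=12,
                           selection_threshold=0.9475, hidden_size=80,
                           max_epochs=500, seed=0, **kwargs) -> BaggedMLPEnsemble:
    """Functional wrapper over :class:`BaggedMLPEnsemble`."""
    ens = BaggedMLPEnsemble(
        n_base=n_base, n_selected=n_selected,
        selection_threshold=selection_threshold, hidden_size=hidden_size,
        max_epochs=max_epochs, random_state=seed, **kwargs)
    return ens.fit(X, y)
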