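"""Classifiers: the small 1-D convolutional network (DCNN) and the SVM /
random-forest baselines, all scikit-learn estimators.

The DCNN treats the flat feature vector as a one-channel 1-D signal and
stacks ``n_conv_layers`` blocks of [conv -> batch-norm -> ReLU -> dropout],
followed by a dense hidden layer and a sigmoid output, trained with Adam on
binary cross-entropy with early stopping on a held-out validation split.
The three tunable hyperparameters are the number of convolutional layers
(1-6), the number of filters (2-128) and the batch size (2-128); dropout is
fixed at 0.2 by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array

from . import _nn

__all__ = [
    "DECISION_THRESHOLD",
    "DCNNClassifier",
    "RbfSVMBaseline",
    "baseline_svm",
    "baseline_rf",
    "grid_search",
    "GridSearchReport",
]

#: Single site of truth for converting class probabilities to labels.
DECISION_THRESHOLD = 0.5

_LAYER_RANGE = (1, 6)
_FILTER_RANGE = (2, 128)
_BATCH_RANGE = (2, 128)


class DCNNClassifier(ClassifierMixin, BaseEstimator):
    """1-D convolutional binary classifier (NumPy implementation).

    Parameters
    ----------
    n_conv_layers, n_filters, batch_size : int
        The three searched hyperparameters; valid ranges 1-6, 2-128, 2-128.
    dropout : float
        Dropout rate after each convolutional block (default 0.2).
    kernel_size : int
        Convolution width (stride 1, same padding).
    dense_units : int
        Width of the hidden dense layer before the sigmoid output.
    max_epochs, early_stop_patience : int
        Training stops after ``max_epochs`` or once validation loss has
        failed to improve for more than ``early_stop_patience`` consecutive
        epochs; the best-validation weights are restored.
    validation_fraction : float
        Fraction of the training data held out (stratified) for early
        stopping.
    learning_rate : float
        Adam step size.
    random_state : int or None
        Seeds weight initialisation, shuffling, dropout and the validation
        split; fits are bit-reproducible single-threaded.

    Attributes
    ----------
    classes_ : ndarray (2,)
    n_epochs_ : int, epochs actually run
    history_ : dict with per-epoch train/validation losses
    """

    def __init__(
        self,
        n_conv_layers: int = 3,
        n_filters: int = 16,
        batch_size: int = 32,
        dropout: float = 0.2,
        kernel_size: int = 3,
        dense_units: int = 64,
        max_epochs: int = 200,
        early_stop_patience: int = 10,
        validation_fraction: float = 0.1,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.n_conv_layers = n_conv_layers
        self.n_filters = n_filters
        self.batch_size = batch_size
        self.dropout = dropout
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    def _check_config(self, input_width: int) -> None:
        for name, value, (lo, hi) in (
            ("n_conv_layers", self.n_conv_layers, _LAYER_RANGE),
            ("n_filters", self.n_filters, _FILTER_RANGE),
            ("batch_size", self.batch_size, _BATCH_RANGE),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside the valid range [{lo}, {hi}]")
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout must be in (0, 1)")
        if input_width < self.kernel_size:
            raise ValueError("input width smaller than the convolution kernel")

    def _build(self, input_width: int, rng: np.random.Generator) -> _nn.Network:
        layers: list[_nn.Layer] = []
        c_in = 1
        for _ in range(self.n_conv_layers):
            layers.append(_nn.Conv1D(c_in, self.n_filters, self.kernel_size, rng))
            layers.append(_nn.BatchNorm(self.n_filters))
            layers.append(_nn.ReLU())
            layers.append(_nn.Dropout(self.dropout, rng))
            c_in = self.n_filters
        layers.append(_nn.Flatten())
        layers.append(_nn.Dense(input_width * c_in, self.dense_units, rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.Dense(self.dense_units, 1, rng))
        return _nn.Network(layers)

    def _val_split(self, y: np.ndarray, rng: np.random.Generator):
        """Stratified validation indices (at least one sample per class)."""
        val_idx = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            n_val = max(1, int(round(self.validation_fraction * len(members))))
            val_idx.append(rng.permutation(members)[:n_val])
        val_idx = np.concatenate(val_idx)
        mask = np.zeros(len(y), dtype=bool)
        mask[val_idx] = True
        return np.flatnonzero(~mask), np.flatnonzero(mask)

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit with early stopping.

        If an explicit validation set is not given, a stratified
        ``validation_fraction`` of (X, y) is held out for it.
        """
        X, y = check_X_y(X, y)
        X = X.astype(np.float32)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y).astype(int)
        if len(self.classes_) != 2:
            raise ValueError("DCNNClassifier is a binary classifier")
        self._check_config(X.shape[1])
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            train_idx, val_idx = self._val_split(y, rng)
            X_val, y_val = X[val_idx], y[val_idx]
            X_tr, y_tr = X[train_idx], y[train_idx]
        else:
            X_val = check_array(X_val)
            y_val = np.asarray(y_val, dtype=float)
            X_tr, y_tr = X, y

        net = self._build(X.shape[1], rng)
        opt = _nn.Adam(net.params(), lr=self.learning_rate)
        n = len(X_tr)
        best_loss, best_weights, best_bn = np.inf, None, None
        since_improve = 0
        history = {"train_loss": [], "val_loss": []}

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X_tr[idx][:, :, None]
                probs = net.forward(xb, training=True)
                if not np.isfinite(probs).all():
                    raise FloatingPointError(
                        f"non-finite activations at epoch {epoch + 1}; "
                        "reduce the learning rate or standardize features"
                    )
                loss = _nn.bce_loss(probs, y_tr[idx])
                epoch_loss += loss * len(idx)
                net.backward(probs, y_tr[idx])
                opt.step()
            val_probs = self._forward_eval(net, X_val)
            val_loss = _nn.bce_loss(val_probs, y_val)
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"NaN validation loss at epoch {epoch + 1}")
            history["train_loss"].append(epoch_loss / n)
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch + 1}: train {epoch_loss / n:.4f} val {val_loss:.4f}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = net.get_weights()
                best_bn = net.bn_state()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve > self.early_stop_patience:
                    break

        if best_weights is not None:
            net.set_weights(best_weights)
            net.set_bn_state(best_bn)
        self.net_ = net
        self.n_epochs_ = len(history["val_loss"])
        self.history_ = history
        self.best_val_loss_ = best_loss
        return self

    def _forward_eval(self, net: _nn.Network, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        X = X.astype(np.float32, copy=False)
        out = np.empty(len(X))
        for start in range(0, len(X), chunk):
            out[start : start + chunk] = net.forward(
                X[start : start + chunk][:, :, None], training=False
            )
        return out

    def predict_proba(self, X):
        X = check_array(X)
        p1 = self._forward_eval(self.net_, X)
        return np.column_stack([1 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= DECISION_THRESHOLD).astype(int)


class RbfSVMBaseline(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM baseline with a logistic link on the margin.

    Wraps :class:`sklearn.svm.SVC` at default settings; probabilities are
    the logistic transform of the decision margin, which preserves the
    ranking (hence ROC/AUC) and makes threshold 0.5 coincide with the SVM's
    own decision boundary.
    """

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y).astype(int)
        self.svc_ = SVC(kernel="rbf", random_state=self.random_state)
        self.svc_.fit(X, y)
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        p1 = expit(self.svc_.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= DECISION_THRESHOLD).astype(int)


def baseline_svm(X, y, random_state: int | None = None) -> RbfSVMBaseline:
    """Fit the RBF-SVM baseline (other parameters at library defaults)."""
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return RbfSVMBaseline(random_state=random_state).fit(X, y)


def baseline_rf(X, y, random_state: int | None = None) -> RandomForestClassifier:
    """Fit the 500-tree random-forest baseline."""
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(n_estimators=500, random_state=random_state, n_jobs=1)
    return rf.fit(X, y)


@dataclass
class GridSearchReport:
    """Per-configuration mean CV MCC and the selected configuration."""

    best_params: dict
    best_score: float
    results: list[dict] = field(default_factory=list)


def _mcc_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    from .evaluation import confusion_metrics

    return confusion_metrics(y_true, y_pred).mcc


def grid_search(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    fold_ids: np.ndarray,
    n_conv_layers=(3,),
    n_filters=(16,),
    batch_size=(32,),
    mode: str = "coordinate",
    resampler=None,
) -> GridSearchReport:
    """Search the three DCNN hyperparameters by cross-validated MCC.

    ``mode="coordinate"`` varies one hyperparameter at a time around the
    estimator's current setting (the protocol behind per-hyperparameter
    bar charts); ``mode="full"`` evaluates the Cartesian product.  Ties are
    broken toward the smaller model (fewer layers, then fewer filters,
    then larger batch).  ``resampler`` (e.g. a SMOTESampler) is applied to
    the training portion of each fold only.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    fold_ids = np.asarray(fold_ids)
    if mode == "full":
        combos = list(itertools.product(n_conv_layers, n_filters, batch_size))
    elif mode == "coordinate":
        base = (estimator.n_conv_layers, estimator.n_filters, estimator.batch_size)
        combos = []
        for axis, values in enumerate((n_conv_layers, n_filters, batch_size)):
            for v in values:
                combo = list(base)
                combo[axis] = v
                combos.append(tuple(combo))
        combos = sorted(set(combos))
    else:
        raise ValueError(f"unknown grid-search mode {mode!r}")
    if not combos:
        raise ValueError("empty hyperparameter grid")

    results = []
    for layers, filters, batch in combos:
        fold_scores = []
        for fold in np.unique(fold_ids):
            tr, te = fold_ids != fold, fold_ids == fold
            X_tr, y_tr = X[tr], y[tr]
            if resampler is not None:
                X_tr, y_tr = clone(resampler).fit_resample(X_tr, y_tr)
            est = clone(estimator).set_params(
                n_conv_layers=layers, n_filters=filters, batch_size=batch
            )
            est.fit(X_tr, y_tr)
            fold_scores.append(_mcc_score(y[te], est.predict(X[te])))
        results.append(
            {
                "n_conv_layers": layers,
                "n_filters": filters,
                "batch_size": batch,
                "mean_mcc": float(np.mean(fold_scores)),
                "fold_mcc": fold_scores,
            }
        )
    best = max(
        results,
        key=lambda r: (
            r["mean_mcc"],
            -r["n_conv_layers"],
            -r["n_filters"],
            r["batch_size"],
        ),
    )
    params = {k: best[k] for k in ("n_conv_layers", "n_filters", "batch_size")}
    return GridSearchReport(best_params=params, best_score=best["mean_mcc"], results=results)
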