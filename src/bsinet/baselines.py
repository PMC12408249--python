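"""Comparator models on concatenated similarity rows.

The classical comparators never see the molecular graph or the sequence
embedding: a pair (i, j) is represented by the i-th row of the fused
small-molecule block concatenated with the j-th row of the fused biotech
block (width 2148 + 196 = 2344 at full scale).  Five families are provided:
SVM, random forest, XGBoost, a three-layer MLP, and a three-block 1-D CNN
(conv + batch-norm + dropout per block, then a dense softmax layer).  All of
them are scored through the same fold plan and evaluation code path as the
graph-attention model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import _autodiff as ad
from ._autodiff import Adam, Tensor

__all__ = ["BaselineSpec", "pair_row_features", "fit_baseline",
           "predict_baseline", "BASELINE_KINDS"]

BASELINE_KINDS = ("svm", "random_forest", "xgboost", "mlp3", "cnn3")


@dataclass
class BaselineSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; "
                             f"choose from {BASELINE_KINDS}")


def pair_row_features(i: int, j: int, ssf: np.ndarray, bbf: np.ndarray) -> np.ndarray:
    """Feature vector of pair (small-molecule i, biotech j): SSf row ‖ BBf row."""
    if not (0 <= i < ssf.shape[0]) or not (0 <= j < bbf.shape[0]):
        raise IndexError(f"pair index ({i}, {j}) out of range")
    return np.concatenate([ssf[i], bbf[j]])


class _CNN1D:
    """Three conv(k=7)+batch-norm+dropout blocks, stride 2, dense softmax."""

    def __init__(self, length: int, n_classes: int, seed: int,
                 channels=(16, 32, 64), kernel: int = 7, stride: int = 2,
                 dropout: float = 0.2, lr: float = 1e-3,
                 epochs: int = 30, batch_size: int = 128):
        self.rng = np.random.default_rng(seed)
        self.dropout, self.lr = dropout, lr
        self.epochs, self.batch_size = epochs, batch_size
        self.stride, self.kernel = stride, kernel
        self.n_classes = n_classes
        self.params: list[Tensor] = []
        self.blocks = []
        c_in, L = 1, length
        for c_out in channels:
            scale = np.sqrt(2.0 / (c_in * kernel + c_out))
            W = Tensor(self.rng.normal(0, scale, (c_out, c_in, kernel)),
                       requires_grad=True)
            b = Tensor(np.zeros(c_out), requires_grad=True)
            g = Tensor(np.ones(c_out), requires_grad=True)
            beta = Tensor(np.zeros(c_out), requires_grad=True)
            running = {"mean": np.zeros(c_out), "var": np.ones(c_out)}
            self.blocks.append((W, b, g, beta, running))
            self.params += [W, b, g, beta]
            L = (L - kernel) // stride + 1
            if L < 1:
                raise ValueError("input too short for the CNN block stack")
            c_in = c_out
        d_flat = c_in * L
        scale = np.sqrt(2.0 / (d_flat + n_classes))
        self.Wd = Tensor(self.rng.normal(0, scale, (d_flat, n_classes)),
                         requires_grad=True)
        self.bd = Tensor(np.zeros(n_classes), requires_grad=True)
        self.params += [self.Wd, self.bd]

    def _logits(self, X: np.ndarray, training: bool) -> Tensor:
        h = Tensor(X[:, None, :])                 # (B, 1, L)
        for W, b, g, beta, running in self.blocks:
            h = ad.conv1d(h, W, b, stride=self.stride)
            h = ad.batch_norm(h, g, beta, running, training)
            h = ad.relu(h)
            h = ad.dropout(h, self.dropout, self.rng, training)
        B = h.shape[0]
        h = h.reshape(B, -1)
        return h @ self.Wd + self.bd

    def fit(self, X: np.ndarray, y: np.ndarray):
        opt = Adam(self.params, lr=self.lr)
        n = len(y)
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                loss = ad.softmax_cross_entropy(self._logits(X[idx], True), y[idx])
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = [ad.softmax(self._logits(X[i:i + 512], False).data)
                 for i in range(0, len(X), 512)]
        return np.concatenate(probs, axis=0)


def _build(spec: BaselineSpec, n_features: int, n_classes: int):
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        # sigmoid-calibrated probabilities for the ranking metrics
        svc = SVC(random_state=spec.seed, **{"C": 1.0, "kernel": "rbf", **hp})
        return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
    if spec.kind == "random_forest":
        return RandomForestClassifier(random_state=spec.seed,
                                      **{"n_estimators": 200, "n_jobs": 1, **hp})
    if spec.kind == "xgboost":
        return XGBClassifier(random_state=spec.seed, num_class=n_classes,
                             **{"n_estimators": 200, "max_depth": 6,
                                "learning_rate": 0.3, "objective": "multi:softprob",
                                "n_jobs": 1, "verbosity": 0, **hp})
    if spec.kind == "mlp3":
        return MLPClassifier(random_state=spec.seed,
                             **{"hidden_layer_sizes": (512, 128),
                                "max_iter": 300, **hp})
    return _CNN1D(length=n_features, n_classes=n_classes, seed=spec.seed, **hp)


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray):
    """Fit one comparator; raises on a degenerate single-class label vector."""
    X, y = np.asarray(X, dtype=np.float64), np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    model = _build(spec, X.shape[1], int(y.max()) + 1)
    model.fit(X, y)
    return model


def predict_baseline(model, X: np.ndarray, n_classes: int | None = None):
    """Class indices and a class-probability matrix with a full-width column
    layout (columns for classes unseen in training are zero)."""
    X = np.asarray(X, dtype=np.float64)
    prob = model.predict_proba(X)
    if n_classes is not None and prob.shape[1] != n_classes:
        full = np.zeros((prob.shape[0], n_classes))
        seen = getattr(model, "classes_", np.arange(prob.shape[1]))
        full[:, np.asarray(seen, dtype=int)] = prob
        prob = full
    return prob.argmax(axis=1), prob
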