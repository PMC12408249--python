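"""Stratified k-fold training loop and the three-regime evaluation suite.

Cross-validation is stratified so that every fold preserves the global class
proportions (within one example per class), which matters for the long-tailed
interaction-class distribution.  Each fold trains until the epoch training
loss falls below the threshold ε or the epoch budget is exhausted; metrics
are computed on the pooled out-of-fold predictions and per fold.

Metrics come in three aggregation regimes:

* micro    — pooled counts over all classes; here precision = recall = F1 =
             accuracy, and MCC is the multiclass correlation coefficient of
             the pooled confusion matrix;
* macro    — unweighted mean of per-class one-vs-rest metrics;
* weighted — support-weighted mean of the same per-class metrics.

AUROC and AUPR are computed one-vs-rest from the class-probability matrix
and aggregated per regime; classes absent from the test labels are skipped
in the macro/weighted ranking metrics with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from ._autodiff import Adam
from .model import BSINet, BSINetConfig, PairExample

__all__ = ["FoldPlan", "MetricsReport", "stratified_folds", "train_fold",
           "evaluate", "run_cv"]

log = logging.getLogger("bsinet")

REGIMES = ("micro", "macro", "weighted")


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray     # fold index per example
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


@dataclass
class MetricsReport:
    """Pooled and per-fold metrics in all three regimes."""

    pooled: dict                      # regime -> {metric: value}
    per_fold: list = field(default_factory=list)   # one dict per fold
    confusion: np.ndarray | None = None
    loss_traces: list = field(default_factory=list)  # per fold: list of epoch losses

    def mean_std(self, regime: str, metric: str) -> tuple[float, float]:
        vals = np.array([f[regime][metric] for f in self.per_fold
                         if not np.isnan(f[regime].get(metric, np.nan))])
        return float(vals.mean()), float(vals.std())


def stratified_folds(labels, k: int, seed: int) -> FoldPlan:
    """Stratified fold assignment; every class must have at least k examples."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    bad = classes[counts < k]
    if len(bad):
        raise ValueError(
            f"classes with fewer than k={k} examples cannot be stratified: "
            f"{bad.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.intp)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def train_fold(train_pairs: list[PairExample], cfg: BSINetConfig,
               seed: int = 0, d_atom: int | None = None) -> tuple[BSINet, list]:
    """Train one model on one training split.

    Minibatch Adam; an epoch ends with the mean training loss E, and training
    stops as soon as E < ε or `max_epochs` epochs have run.  Returns the
    model and the per-epoch loss trace.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    if d_atom is None:
        d_atom = train_pairs[0].graph.node_features.shape[1]
    model = BSINet(cfg, d_atom=d_atom, seed=seed)
    if cfg.max_epochs <= 0:
        return model, []
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)
    n = len(train_pairs)
    trace: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, sizes = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [train_pairs[i] for i in idx]
            labels = np.array([p.label for p in batch])
            opt.zero_grad()
            _, loss = model.forward_batch(batch, training=True, labels=labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            sizes.append(len(idx))
        epoch_loss = float(np.average(losses, weights=sizes))
        trace.append(epoch_loss)
        log.info("epoch %d: training loss %.4f", epoch, epoch_loss)
        if epoch_loss < cfg.epsilon:
            break
    return model, trace


def _ovr_ranking(y_true: np.ndarray, prob: np.ndarray, regime: str,
                 scorer) -> float:
    """One-vs-rest AUROC/AUPR aggregated per regime over classes present."""
    present = np.unique(y_true)
    n_classes = prob.shape[1]
    skipped = [c for c in range(n_classes) if c not in present]
    if skipped:
        log.warning("classes absent from y_true skipped in ranking metrics: %s",
                    skipped)
    per_class, support = [], []
    for c in present:
        ind = (y_true == c).astype(int)
        if ind.all():               # degenerate: only one class present overall
            return float("nan")
        per_class.append(scorer(ind, prob[:, c]))
        support.append(ind.sum())
    per_class, support = np.array(per_class), np.array(support)
    if regime == "micro":
        ind_flat = np.concatenate([(y_true == c).astype(int) for c in present])
        score_flat = np.concatenate([prob[:, c] for c in present])
        return float(scorer(ind_flat, score_flat))
    if regime == "macro":
        return float(per_class.mean())
    return float(np.average(per_class, weights=support))


def evaluate(y_true, y_pred, prob_matrix, regime: str) -> dict:
    """Metric slice for one aggregation regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    prob_matrix = np.asarray(prob_matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = skm.precision_recall_fscore_support(
            y_true, y_pred, average=regime, zero_division=0)
    out = {"precision": float(prec), "recall": float(rec), "f1": float(f1),
           "auroc": _ovr_ranking(y_true, prob_matrix, regime, skm.roc_auc_score),
           "aupr": _ovr_ranking(y_true, prob_matrix, regime,
                                skm.average_precision_score)}
    if regime == "micro":
        out["mcc"] = float(skm.matthews_corrcoef(y_true, y_pred))
        out["accuracy"] = float(skm.accuracy_score(y_true, y_pred))
    return out


def _score_all(y_true, y_pred, prob, n_classes: int) -> dict:
    report = {r: evaluate(y_true, y_pred, prob, r) for r in REGIMES}
    report["confusion"] = skm.confusion_matrix(
        y_true, y_pred, labels=np.arange(n_classes))
    return report


def run_cv(pairs: list[PairExample], cfg: BSINetConfig, k: int = 10,
           seed: int = 0, trainer=None) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring.

    `trainer(train_pairs, test_pairs, fold_seed)` may override the model
    family (used for the classical baselines); it must return
    (probability matrix, loss trace) for the test pairs.  By default the
    graph-attention network is trained via :func:`train_fold`.
    """
    labels = np.array([p.label for p in pairs])
    plan = stratified_folds(labels, k, seed)
    n = len(pairs)
    pooled_prob = np.zeros((n, cfg.n_classes))
    per_fold, traces = [], []
    for fold in range(k):
        train_idx, test_idx = plan.split(fold)
        train_pairs = [pairs[i] for i in train_idx]
        test_pairs = [pairs[i] for i in test_idx]
        fold_seed = (seed * 1000 + fold) % (2**31 - 1)
        if trainer is None:
            model, trace = train_fold(train_pairs, cfg, seed=fold_seed)
            prob = _predict_in_chunks(model, test_pairs, cfg.batch_size)
        else:
            prob, trace = trainer(train_pairs, test_pairs, fold_seed)
        pooled_prob[test_idx] = prob
        y_pred = prob.argmax(axis=1)
        per_fold.append(_score_all(labels[test_idx], y_pred, prob, cfg.n_classes))
        traces.append(trace)
        log.info("fold %d/%d: weighted F1 %.4f", fold + 1, k,
                 per_fold[-1]["weighted"]["f1"])
    pooled_pred = pooled_prob.argmax(axis=1)
    pooled = _score_all(labels, pooled_pred, pooled_prob, cfg.n_classes)
    confusion = pooled.pop("confusion")
    return MetricsReport(pooled=pooled,
                         per_fold=[{r: f[r] for r in REGIMES} for f in per_fold],
                         confusion=confusion, loss_traces=traces)


def _predict_in_chunks(model: BSINet, pairs: list[PairExample],
                       batch_size: int) -> np.ndarray:
    chunks = [model.forward_batch(pairs[i:i + batch_size], training=False)
              for i in range(0, len(pairs), batch_size)]
    return np.concatenate(chunks, axis=0)
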