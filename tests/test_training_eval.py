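"""Stratified folds, the training loop, and the three-regime metric suite."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from bsinet.model import BSINetConfig
from bsinet.training_eval import (evaluate, run_cv, stratified_folds,
                                  train_fold)


# ------------------------------------------------------------------ folds --

def test_single_class_exact_split():
    plan = stratified_folds([0] * 100, k=10, seed=0)
    counts = np.bincount(plan.assignments, minlength=10)
    np.testing.assert_array_equal(counts, 10)


def test_divisible_class_counts_split_exactly():
    labels = np.repeat([0, 1, 2], [50, 30, 20])
    plan = stratified_folds(labels, k=10, seed=1)
    for fold in range(10):
        fold_labels = labels[plan.assignments == fold]
        np.testing.assert_array_equal(np.bincount(fold_labels, minlength=3),
                                      [5, 3, 2])


def test_fold_class_frequencies_within_one_example(rng):
    labels = rng.integers(0, 5, size=237)
    # ensure feasibility
    labels[:25] = np.repeat(np.arange(5), 5)
    k = 5
    plan = stratified_folds(labels, k=k, seed=3)
    global_counts = np.bincount(labels, minlength=5)
    for fold in range(k):
        fold_counts = np.bincount(labels[plan.assignments == fold], minlength=5)
        assert np.all(np.abs(fold_counts - global_counts / k) <= 1.0)


def test_two_seeds_differ_but_preserve_counts():
    labels = np.repeat([0, 1, 2], [50, 30, 20])
    a = stratified_folds(labels, k=10, seed=0)
    b = stratified_folds(labels, k=10, seed=99)
    assert not np.array_equal(a.assignments, b.assignments)
    for fold in range(10):
        np.testing.assert_array_equal(
            np.bincount(labels[a.assignments == fold], minlength=3),
            np.bincount(labels[b.assignments == fold], minlength=3))


def test_small_class_raises_with_offenders_listed():
    with pytest.raises(ValueError, match=r"\[2\]"):
        stratified_folds([0] * 20 + [1] * 20 + [2] * 3, k=5, seed=0)


# ------------------------------------------------------------------ training --

def test_epsilon_above_initial_loss_stops_after_one_epoch(tiny_pairs, tiny_model_cfg):
    import dataclasses
    cfg = dataclasses.replace(tiny_model_cfg, epsilon=100.0, max_epochs=5)
    _, trace = train_fold(tiny_pairs[:64], cfg, seed=0)
    assert len(trace) == 1


def test_zero_epoch_budget_returns_untrained_model(tiny_pairs, tiny_model_cfg):
    import dataclasses
    cfg = dataclasses.replace(tiny_model_cfg, max_epochs=0)
    model, trace = train_fold(tiny_pairs[:32], cfg, seed=0)
    assert trace == []
    assert model is not None


def test_loss_trace_decreases_on_separable_planted_data(tiny_pairs, tiny_model_cfg):
    import dataclasses
    cfg = dataclasses.replace(tiny_model_cfg, max_epochs=5, epsilon=0.0,
                              dropout=0.0)
    _, trace = train_fold(tiny_pairs, cfg, seed=0)
    assert len(trace) >= 2
    assert trace[-1] < trace[0]


def test_empty_training_set_rejected(tiny_model_cfg):
    with pytest.raises(ValueError):
        train_fold([], tiny_model_cfg)


# ------------------------------------------------------------------ metrics --

def _perfect(n=60, C=3, rng=None):
    rng = rng or np.random.default_rng(0)
    y = rng.integers(0, C, size=n)
    prob = np.zeros((n, C))
    prob[np.arange(n), y] = 1.0
    return y, y.copy(), prob


def test_perfect_predictions_score_one_everywhere():
    y_true, y_pred, prob = _perfect()
    for regime in ("micro", "macro", "weighted"):
        m = evaluate(y_true, y_pred, prob, regime)
        assert m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["auroc"] == pytest.approx(1.0)
        assert m["aupr"] == pytest.approx(1.0)
    assert evaluate(y_true, y_pred, prob, "micro")["mcc"] == 1.0


def test_macro_metrics_match_hand_computed_toy_confusion():
    # confusion [[2,0,0],[1,1,0],[0,0,2]]
    y_true = np.array([0, 0, 1, 1, 2, 2])
    y_pred = np.array([0, 0, 0, 1, 2, 2])
    prob = np.zeros((6, 3))
    prob[np.arange(6), y_pred] = 1.0
    m = evaluate(y_true, y_pred, prob, "macro")
    assert m["precision"] == pytest.approx((2 / 3 + 1.0 + 1.0) / 3)
    assert m["recall"] == pytest.approx((1.0 + 0.5 + 1.0) / 3)


def test_micro_identities_hold_in_all_class_multiclass(rng):
    y_true = rng.integers(0, 4, size=200)
    y_pred = rng.integers(0, 4, size=200)
    prob = rng.dirichlet(np.ones(4), size=200)
    micro = evaluate(y_true, y_pred, prob, "micro")
    acc = (y_true == y_pred).mean()
    assert micro["precision"] == pytest.approx(acc)
    assert micro["recall"] == pytest.approx(acc)
    assert micro["f1"] == pytest.approx(acc)
    assert micro["accuracy"] == pytest.approx(acc)
    # weighted recall equals accuracy when every class is scored
    weighted = evaluate(y_true, y_pred, prob, "weighted")
    assert weighted["recall"] == pytest.approx(acc)


def test_random_predictions_give_near_zero_mcc(rng):
    n = 4000
    y_true = rng.integers(0, 4, size=n)
    y_pred = rng.integers(0, 4, size=n)
    prob = np.full((n, 4), 0.25)
    m = evaluate(y_true, y_pred, prob, "micro")
    assert abs(m["mcc"]) < 0.05


def test_multiclass_mcc_reduces_to_binary_mcc(rng):
    y_true = rng.integers(0, 2, size=120)
    y_pred = rng.integers(0, 2, size=120)
    prob = np.zeros((120, 2))
    prob[np.arange(120), y_pred] = 1.0
    m = evaluate(y_true, y_pred, prob, "micro")
    assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))


def test_unknown_regime_rejected():
    with pytest.raises(ValueError):
        evaluate([0, 1], [0, 1], np.eye(2), "median")


# ------------------------------------------------------------------ run_cv --

def test_cv_covers_every_example_once_and_is_reproducible(tiny_pairs, tiny_model_cfg):
    import dataclasses
    cfg = dataclasses.replace(tiny_model_cfg, max_epochs=1)
    covered = np.zeros(len(tiny_pairs), dtype=int)

    def trainer(train_pairs, test_pairs, fold_seed):
        for p in test_pairs:
            covered[tiny_pairs.index(p)] += 1
        n = len(test_pairs)
        rng = np.random.default_rng(fold_seed)
        return rng.dirichlet(np.ones(cfg.n_classes), size=n), [1.0]

    rep1 = run_cv(tiny_pairs, cfg, k=2, seed=5, trainer=trainer)
    assert (covered == 1).all()
    covered[:] = 0
    rep2 = run_cv(tiny_pairs, cfg, k=2, seed=5, trainer=trainer)
    assert rep1.pooled == rep2.pooled
    np.testing.assert_array_equal(rep1.confusion, rep2.confusion)
    assert rep1.confusion.sum() == len(tiny_pairs)
    # confusion row sums equal per-class test counts
    labels = np.array([p.label for p in tiny_pairs])
    np.testing.assert_array_equal(rep1.confusion.sum(axis=1),
                                  np.bincount(labels, minlength=cfg.n_classes))


def test_cv_trains_the_network_end_to_end(tiny_pairs, tiny_model_cfg):
    import dataclasses
    cfg = dataclasses.replace(tiny_model_cfg, max_epochs=15)
    rep = run_cv(tiny_pairs, cfg, k=2, seed=0)
    assert rep.pooled["weighted"]["f1"] > 0.8     # planted rule is learnable
    mean, std = rep.mean_std("weighted", "f1")
    assert 0.0 <= mean <= 1.0 and std >= 0.0
    assert len(rep.loss_traces) == 2
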