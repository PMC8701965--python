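import math

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from circmil.instancing import WindowGeometry, extract_instances
from circmil.model import BagNet, ModelConfig
from circmil.synthetic import SeqSimConfig, simulate_sequences
from circmil.training import (EncodedBag, TrainConfig, confusion, encode_bags,
                              evaluate, f1, mcc, predict_probs,
                              pretrain_masked_lm, roc_auc, train)

# -- metric oracles --------------------------------------------------------


def test_confusion_worked_cases():
    assert confusion([1, 0], [0.9, 0.1]) == (1, 1, 0, 0)
    assert confusion([1, 0], [0.1, 0.9]) == (0, 0, 1, 1)
    # probability exactly at threshold counts as a positive call
    assert confusion([1, 0], [0.5, 0.5]) == (1, 0, 1, 0)
    with pytest.raises(ValueError):
        confusion([1, 0], [0.5])


def test_mcc_worked_cases():
    assert mcc(50, 50, 0, 0) == pytest.approx(1.0)
    assert mcc(25, 25, 25, 25) == pytest.approx(0.0)
    assert mcc(6, 3, 1, 2) == pytest.approx(0.478, abs=1e-3)
    assert mcc(5, 0, 0, 0) == 0.0     # degenerate denominator convention


def test_f1_worked_cases():
    assert f1(9, 1, 1) == pytest.approx(0.9)
    assert f1(6, 1, 2) == pytest.approx(0.8)   # precision 6/7, recall 6/8
    assert f1(0, 3, 4) == 0.0
    assert f1(0, 0, 0) == 0.0


def brute_mcc(tp, tn, fp, fn):
    num = tp * tn - fp * fn
    den = math.sqrt(tp + fp) * math.sqrt(tp + fn) * math.sqrt(tn + fp) * math.sqrt(tn + fn)
    return 0.0 if den == 0 else num / den


def brute_f1(tp, fp, fn):
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def test_mcc_f1_match_bruteforce_on_random_matrices(rng):
    for _ in range(1000):
        tp, tn, fp, fn = (int(x) for x in rng.integers(0, 200, 4))
        assert mcc(tp, tn, fp, fn) == pytest.approx(brute_mcc(tp, tn, fp, fn), abs=1e-9)
        assert f1(tp, fp, fn) == pytest.approx(brute_f1(tp, fp, fn), abs=1e-9)


def test_mcc_agrees_with_sklearn(rng):
    """Cross-check against an independent library implementation."""
    for _ in range(50):
        y = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        if len(np.unique(y)) < 2 or len(np.unique(p)) < 2:
            continue
        tp = int(np.sum((y == 1) & (p == 1)))
        tn = int(np.sum((y == 0) & (p == 0)))
        fp = int(np.sum((y == 0) & (p == 1)))
        fn = int(np.sum((y == 1) & (p == 0)))
        assert mcc(tp, tn, fp, fn) == pytest.approx(matthews_corrcoef(y, p), abs=1e-9)
        assert f1(tp, fp, fn) == pytest.approx(f1_score(y, p), abs=1e-9)


def test_mcc_symmetries(rng):
    for _ in range(50):
        tp, tn, fp, fn = (int(x) for x in rng.integers(1, 100, 4))
        # swapping classes and predictions together leaves MCC unchanged
        assert mcc(tp, tn, fp, fn) == pytest.approx(mcc(tn, tp, fn, fp), abs=1e-12)
        # negating predictions negates MCC
        assert mcc(fp, fn, tp, tn) == pytest.approx(-mcc(tp, tn, fp, fn), abs=1e-12)


def pairwise_auc(labels, probs):
    """Oracle: fraction of positive-negative pairs ranked correctly."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_worked_cases(rng):
    auc, _, _ = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
    assert auc == pytest.approx(0.75)
    assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        roc_auc([1, 1], [0.5, 0.6])


def test_roc_auc_matches_pairwise_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(6, 40))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        probs = np.round(rng.random(n), 2)   # ties included
        auc, _, _ = roc_auc(labels, probs)
        assert auc == pytest.approx(pairwise_auc(labels, probs), abs=1e-9)


def test_roc_auc_invariant_under_monotone_transform(rng):
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]
    probs = rng.random(60)
    a1, _, _ = roc_auc(labels, probs)
    a2, _, _ = roc_auc(labels, np.exp(3 * probs))
    assert a2 == pytest.approx(a1, abs=1e-12)


def test_roc_auc_random_scores_near_half(rng):
    labels = rng.integers(0, 2, 2000)
    probs = rng.random(2000)
    assert roc_auc(labels, probs)[0] == pytest.approx(0.5, abs=0.05)


def test_evaluate_report_fields():
    rep = evaluate([1, 1, 0, 0], [0.9, 0.4, 0.2, 0.6])
    assert (rep.TP, rep.TN, rep.FP, rep.FN) == (1, 1, 1, 1)
    assert rep.TP + rep.TN + rep.FP + rep.FN == 4
    assert -1.0 <= rep.mcc <= 1.0
    assert 0.0 <= rep.f1 <= 1.0
    d = rep.to_dict()
    assert set(d) == {"TP", "TN", "FP", "FN", "accuracy", "sensitivity",
                      "specificity", "precision", "mcc", "f1", "auc"}


# -- training loop ---------------------------------------------------------


def _separable_bags(rng, n=24, k=4, t=12):
    """Trivially separable synthetic bags: positives are all-A windows."""
    bags = []
    for i in range(n):
        label = i % 2
        if label:
            x = np.zeros((k, t), dtype=np.int64)
        else:
            x = rng.integers(1, 4, size=(k, t))
        bags.append(EncodedBag(x=x, label=label, record_id=f"b{i}"))
    return bags


def _tiny_net():
    return BagNet(ModelConfig(rnn_hidden=6, fcn_hidden=8, feature_dim=5,
                              attention_hidden=4), seed=0)


def test_train_reduces_loss_on_separable_data(rng):
    bags = _separable_bags(rng)
    net = _tiny_net()
    cfg = TrainConfig(lr=3e-3, epochs=25, batch_bags=8, selection="last", seed=0)
    result = train(net, bags, None, cfg)
    hist = result.history
    assert len(hist) == 25
    assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]
    assert hist.train_acc.iloc[-1] > 0.9


def test_train_is_deterministic_under_seed(rng):
    bags = _separable_bags(rng)
    cfg = TrainConfig(lr=1e-3, epochs=2, batch_bags=8, selection="last", seed=5)
    r1 = train(_tiny_net(), bags, None, cfg)
    r2 = train(_tiny_net(), bags, None, cfg)
    assert r1.history.train_loss.iloc[0] == r2.history.train_loss.iloc[0]
    assert r1.history.equals(r2.history)


def test_train_rejects_single_class(rng):
    bags = [b for b in _separable_bags(rng) if b.label == 1]
    with pytest.raises(ValueError, match="both classes"):
        train(_tiny_net(), bags, None, TrainConfig(epochs=1))


def test_validation_history_and_selection(rng):
    bags = _separable_bags(rng, n=32)
    cfg = TrainConfig(lr=3e-3, epochs=4, batch_bags=8, selection="best_val", seed=1)
    result = train(_tiny_net(), bags[:24], bags[24:], cfg)
    assert not result.history.val_auc.isna().any()
    assert 1 <= result.best_epoch <= 4


def test_max_pool_warmup_path_runs(rng):
    bags = _separable_bags(rng, n=16)
    cfg = TrainConfig(lr=3e-3, epochs=3, batch_bags=8, selection="last",
                      warmup_epochs=2, seed=0)
    result = train(_tiny_net(), bags, None, cfg)
    assert len(result.history) == 3


def test_masked_lm_pretraining_reduces_loss(rng):
    recs, _ = simulate_sequences(SeqSimConfig(n_pos=8, n_neg=8, seed=3))
    bags = encode_bags([extract_instances(r, WindowGeometry(20, 10)) for r in recs])
    net = _tiny_net()
    losses = pretrain_masked_lm(net, bags, epochs=2, lr=3e-3, seed=0)
    assert len(losses) == 2
    assert losses[-1] <= losses[0]


def test_predict_probs_chunking_consistent(rng):
    bags = _separable_bags(rng, n=10)
    net = _tiny_net()
    p1 = predict_probs(net, bags, max_instances=4)
    p2 = predict_probs(net, bags, max_instances=4096)
    np.testing.assert_allclose(p1, p2, atol=1e-6)
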