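import numpy as np
import pytest

from protloc.metrics import (
    ConfusionCounts,
    ThresholdSet,
    attention_signal_kl,
    auc_per_label,
    decide,
    evaluate,
    fit_thresholds,
    mcc,
)


# ---------------------------------------------------------------- oracles

def naive_multilabel_metrics(decided, truth):
    """Independent naive-loop implementation of the whole metric suite."""
    n, C = decided.shape
    exact = sum(1 for i in range(n) if all(decided[i, c] == truth[i, c]
                                           for c in range(C))) / n
    jac = 0.0
    for i in range(n):
        inter = sum(1 for c in range(C) if decided[i, c] and truth[i, c])
        union = sum(1 for c in range(C) if decided[i, c] or truth[i, c])
        jac += 1.0 if union == 0 else inter / union
    jac /= n
    tp = fp = fn = 0
    per_f1 = []
    per_mcc = []
    for c in range(C):
        tpc = sum(1 for i in range(n) if decided[i, c] and truth[i, c])
        fpc = sum(1 for i in range(n) if decided[i, c] and not truth[i, c])
        fnc = sum(1 for i in range(n) if not decided[i, c] and truth[i, c])
        tnc = n - tpc - fpc - fnc
        tp += tpc; fp += fpc; fn += fnc
        per_f1.append(0.0 if 2 * tpc + fpc + fnc == 0
                      else 2 * tpc / (2 * tpc + fpc + fnc))
        denom = (tpc + fpc) * (tpc + fnc) * (tnc + fpc) * (tnc + fnc)
        per_mcc.append(0.0 if denom == 0
                       else (tpc * tnc - fpc * fnc) / np.sqrt(denom))
    micro = 0.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    macro = sum(per_f1) / C
    mean_count = sum(decided[i].sum() for i in range(n)) / n
    return exact, jac, micro, macro, np.array(per_mcc), mean_count


def naive_auc(scores, targets):
    pos = scores[targets == 1]
    neg = scores[targets == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_best_mcc(scores, targets):
    """Max MCC over every achievable >=-threshold decision partition."""
    best = -np.inf
    for tau in np.concatenate((np.unique(scores), [0.0, 1.0, 2.0])):
        pred = (scores >= tau).astype(int)
        tp = int(np.sum(pred & targets))
        fp = int(np.sum(pred & (1 - targets)))
        fn = int(np.sum((1 - pred) & targets))
        tn = len(targets) - tp - fp - fn
        best = max(best, mcc(ConfusionCounts(tp, fp, tn, fn)))
    return best


# ------------------------------------------------------------------- mcc

def test_mcc_perfect_classifier():
    assert mcc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0


def test_mcc_perfect_anticlassifier():
    assert mcc(ConfusionCounts(tp=0, fp=5, tn=0, fn=5)) == -1.0


def test_mcc_direct_formula_case():
    value = mcc(ConfusionCounts(tp=45, fp=10, tn=40, fn=5))
    expected = (45 * 40 - 10 * 5) / np.sqrt(55 * 50 * 50 * 45)
    assert value == pytest.approx(expected, abs=1e-15)
    assert value == pytest.approx(0.7035, abs=1e-4)


def test_mcc_zero_when_denominator_vanishes():
    assert mcc(ConfusionCounts(tp=0, fp=0, tn=10, fn=0)) == 0.0


# ------------------------------------------------------------ thresholds

def test_thresholds_separate_perfectly_separable_scores(rng):
    n = 40
    targets = np.zeros((n, 1), dtype=int)
    targets[: n // 2] = 1
    scores = np.where(targets == 1, 0.7, 0.2) + rng.random((n, 1)) * 0.05
    ts = fit_thresholds(scores, targets)
    pred = (scores >= ts.tau).astype(int)
    assert np.array_equal(pred, targets)


def test_thresholds_match_exhaustive_partition_scan(rng):
    for _ in range(10):
        n = int(rng.integers(5, 60))
        scores = rng.random((n, 3))
        targets = rng.integers(0, 2, size=(n, 3))
        if any(targets[:, c].min() == targets[:, c].max() for c in range(3)):
            continue
        ts = fit_thresholds(scores, targets)
        for c in range(3):
            pred = (scores[:, c] >= ts.tau[c]).astype(int)
            tp = int(np.sum(pred & targets[:, c]))
            fp = int(np.sum(pred & (1 - targets[:, c])))
            fn = int(np.sum((1 - pred) & targets[:, c]))
            tn = n - tp - fp - fn
            achieved = mcc(ConfusionCounts(tp, fp, tn, fn))
            assert achieved == pytest.approx(
                brute_force_best_mcc(scores[:, c], targets[:, c]), abs=1e-12
            )


def test_thresholds_degenerate_identical_scores():
    scores = np.full((10, 1), 0.5)
    targets = np.array([[1]] * 5 + [[0]] * 5)
    ts = fit_thresholds(scores, targets)
    # only the trivial partitions exist; tie rule picks the smallest tau
    assert ts.tau[0] == 0.0


def test_thresholds_single_class_label_defaults():
    scores = np.random.default_rng(0).random((10, 1))
    targets = np.ones((10, 1), dtype=int)
    assert fit_thresholds(scores, targets).tau[0] == 0.5


# ----------------------------------------------------------------- decide

def test_decide_above_threshold():
    preds = decide(np.array([[0.9, 0.1]]), ThresholdSet(np.array([0.5, 0.5])))
    assert np.array_equal(preds[0].decided, [1, 0])
    assert not preds[0].fallback_used


def test_decide_fallback_picks_closest_label():
    preds = decide(np.array([[0.3, 0.4]]), ThresholdSet(np.array([0.5, 0.5])))
    assert np.array_equal(preds[0].decided, [0, 1])
    assert preds[0].fallback_used


def test_decide_threshold_equality_is_inclusive():
    preds = decide(np.array([[0.5, 0.1]]), ThresholdSet(np.array([0.5, 0.5])))
    assert preds[0].decided[0] == 1
    assert not preds[0].fallback_used


def test_decide_fallback_tie_breaks_to_lowest_index():
    preds = decide(np.array([[0.2, 0.2]]), ThresholdSet(np.array([0.5, 0.5])))
    assert np.array_equal(preds[0].decided, [1, 0])


# --------------------------------------------------------------- evaluate

def test_perfect_predictions_score_one(rng):
    truth = rng.integers(0, 2, size=(20, 5))
    truth[truth.sum(axis=1) == 0, 0] = 1
    rep = evaluate(truth, truth)
    assert rep.exact_match_accuracy == 1.0
    assert rep.jaccard == 1.0
    assert rep.micro_f1 == 1.0
    assert rep.macro_f1 == 1.0
    assert np.all(rep.mcc_per_label == 1.0)


def test_two_sample_hand_case():
    truth = np.array([[1, 0], [1, 1]])      # {A}, {A,B}
    decided = np.array([[1, 0], [0, 1]])    # {A}, {B}
    rep = evaluate(decided, truth)
    assert rep.exact_match_accuracy == 0.5
    assert rep.jaccard == pytest.approx((1 + 0.5) / 2)


def test_metrics_match_naive_loop_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(2, 50))
        truth = rng.integers(0, 2, size=(n, 10))
        decided = rng.integers(0, 2, size=(n, 10))
        rep = evaluate(decided, truth)
        exact, jac, micro, macro, per_mcc, mean_count = \
            naive_multilabel_metrics(decided, truth)
        assert rep.exact_match_accuracy == pytest.approx(exact, abs=1e-12)
        assert rep.jaccard == pytest.approx(jac, abs=1e-12)
        assert rep.micro_f1 == pytest.approx(micro, abs=1e-12)
        assert rep.macro_f1 == pytest.approx(macro, abs=1e-12)
        assert np.allclose(rep.mcc_per_label, per_mcc, atol=1e-12)
        assert rep.mean_predicted_labels == pytest.approx(mean_count, abs=1e-12)


# ---------------------------------------------------------------- KL, AUC

def test_kl_zero_when_attention_equals_target():
    mask = np.array([1, 1, 0, 0])
    a = np.array([0.5, 0.5, 0.0, 0.0])
    assert attention_signal_kl(a, mask) == pytest.approx(0.0, abs=1e-12)


def test_kl_uniform_attention_half_mask_is_log_two():
    L = 10
    a = np.full(L, 1 / L)
    mask = np.zeros(L)
    mask[:5] = 1
    assert attention_signal_kl(a, mask) == pytest.approx(np.log(2), abs=1e-12)


def test_kl_decreases_as_attention_concentrates_in_mask():
    L = 10
    mask = np.zeros(L)
    mask[:5] = 1
    uniform = np.full(L, 1 / L)
    concentrated = np.where(mask > 0, 0.18, 0.02)
    assert attention_signal_kl(concentrated, mask) < \
        attention_signal_kl(uniform, mask)


def test_kl_empty_mask_is_undefined():
    with pytest.raises(ValueError):
        attention_signal_kl(np.full(4, 0.25), np.zeros(4))


def test_auc_separable_and_null(rng):
    targets = np.array([[1]] * 10 + [[0]] * 10)
    scores = np.where(targets == 1, 0.9, 0.1)
    assert auc_per_label(scores, targets)[0] == 1.0
    big_targets = rng.integers(0, 2, size=(4000, 1))
    big_scores = rng.random((4000, 1))
    assert auc_per_label(big_scores, big_targets)[0] == pytest.approx(0.5, abs=0.05)


def test_auc_matches_pair_counting_oracle(rng):
    scores = np.round(rng.random((30, 2)), 1)  # rounding forces ties
    targets = rng.integers(0, 2, size=(30, 2))
    targets[0] = 1
    targets[1] = 0
    aucs = auc_per_label(scores, targets)
    for c in range(2):
        assert aucs[c] == pytest.approx(
            naive_auc(scores[:, c], targets[:, c]), abs=1e-12
        )
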