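"""Every scalar score is checked against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxalert.metrics import (
    ConfusionCounts,
    accuracy,
    cohen_kappa,
    confusion,
    evaluate,
    f1_score,
    mcc,
    precision,
    recall,
    roc_auc,
)

# ---------------------------------------------------------------- oracles


def brute_confusion(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def brute_auc(scores, y_true):
    wins = ties = 0
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_kappa(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) / n) * ((tp + fn) / n) + ((tn + fn) / n) * ((tn + fp) / n)
    return (po - pe) / (1 - pe) if pe != 1 else 0.0


# ---------------------------------------------------------------- exact cases


def test_confusion_perfect_and_inverted():
    y = [0, 1, 1, 0, 1]
    c = confusion(y, y)
    assert (c.fp, c.fn) == (0, 0)
    c = confusion(y, [1 - v for v in y])
    assert (c.tp, c.tn) == (0, 0)


def test_confusion_input_validation():
    with pytest.raises(ValueError):
        confusion([0, 1], [0])
    with pytest.raises(ValueError):
        confusion([0, 2], [0, 1])


@pytest.mark.parametrize("p,r,expected", [
    (0.7, 0.7, 0.7),          # harmonic-mean identity at p = r
    (1.0, 0.0, 0.0),
    (0.0, 0.0, 0.0),
])
def test_f1_edge_cases(p, r, expected):
    assert f1_score(p, r) == pytest.approx(expected)


def test_f1_published_precision_recall_pair():
    # printed external-test scores for the PPAR model: p=0.993, r=0.989 → F1 0.991
    assert round(f1_score(0.993, 0.989), 3) == 0.991


def test_mcc_extremes_and_formula():
    assert mcc(ConfusionCounts(5, 0, 5, 0)) == 1.0
    assert mcc(ConfusionCounts(0, 5, 0, 5)) == -1.0
    expected = 7000 / math.sqrt(100 * 110 * 90 * 100)
    assert mcc(ConfusionCounts(90, 10, 80, 20)) == pytest.approx(expected)
    assert mcc(ConfusionCounts(3, 0, 0, 0)) == 0.0  # degenerate → 0 by convention


def test_kappa_extremes():
    assert cohen_kappa(ConfusionCounts(5, 0, 5, 0)) == 1.0
    # one-class prediction on balanced truth is chance level
    assert cohen_kappa(confusion([0, 1, 0, 1], [1, 1, 1, 1])) == pytest.approx(0.0)


def test_roc_auc_exact_cases():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    assert roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75  # 3 of 4 pairs
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------- oracle sweeps


def test_all_metrics_match_brute_force_on_random_sets():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(10, 120))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        pred = rng.integers(0, 2, n)
        scores = np.round(rng.random(n), 2)  # coarse grid forces score ties
        tp, fp, tn, fn = brute_confusion(y, pred)
        c = confusion(y, pred)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert precision(c) == pytest.approx(tp / (tp + fp) if tp + fp else 0.0, abs=1e-12)
        assert recall(c) == pytest.approx(tp / (tp + fn) if tp + fn else 0.0, abs=1e-12)
        assert accuracy(c) == pytest.approx((tp + tn) / n, abs=1e-12)
        assert cohen_kappa(c) == pytest.approx(brute_kappa(tp, fp, tn, fn), abs=1e-12)
        assert roc_auc(scores, y) == pytest.approx(brute_auc(scores, y), abs=1e-12)


def test_metrics_match_sklearn():
    from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

    rng = np.random.default_rng(1)
    for _ in range(20):
        y = rng.integers(0, 2, 80)
        if len(np.unique(y)) < 2:
            continue
        pred = rng.integers(0, 2, 80)
        scores = rng.random(80)
        c = confusion(y, pred)
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert cohen_kappa(c) == pytest.approx(cohen_kappa_score(y, pred), abs=1e-12)
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


# ---------------------------------------------------------------- properties


@settings(deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0.001, 0.999)),
                min_size=4, max_size=60))
def test_auc_complement_symmetry(pairs):
    y = [t for t, _ in pairs]
    s = [v for _, v in pairs]
    if len(set(y)) < 2 or len(set(s)) < len(s):
        return  # needs both classes and tie-free scores
    assert roc_auc(s, y) + roc_auc(s, [1 - t for t in y]) == pytest.approx(1.0)


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 40)
    if len(np.unique(y)) < 2:
        return
    scores = rng.random(40)
    perm = rng.permutation(40)
    r1 = evaluate(scores, y)
    r2 = evaluate(scores[perm], y[perm])
    for attr in ("precision", "recall", "f1", "accuracy", "mcc", "kappa", "roc_auc"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-12)


def test_report_ranges():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    rep = evaluate(rng.random(50), y, task="AR")
    for v in (rep.precision, rep.recall, rep.f1, rep.accuracy, rep.roc_auc):
        assert 0.0 <= v <= 1.0
    assert -1.0 <= rep.mcc <= 1.0 and -1.0 <= rep.kappa <= 1.0
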