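"""Evaluation metrics against independent brute-force oracles.

Oracles: set-overlap formulas on explicit foreground sets for ACC/DSC/IoU,
all-pairs Euclidean distances for the average Hausdorff distance, and
exhaustive pairwise win/tie counting for AUC (cross-checked against
scikit-learn).
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rdaunet.errors import PairingError, UndefinedMetricError
from rdaunet.metrics import (ConfusionCounts, confusion_counts, accuracy,
                             dice, iou, avg_hausdorff, roc_auc, evaluate_pair)


# ------------------------------------------------------------------ oracles

def overlap_oracle(pred, gt):
    """ACC/DSC/IoU from explicit foreground coordinate sets."""
    a = {tuple(p) for p in np.argwhere(pred)}
    b = {tuple(p) for p in np.argwhere(gt)}
    n = pred.size
    inter, union = len(a & b), len(a | b)
    acc = (inter + (n - union)) / n
    dsc = 1.0 if not a and not b else 2 * inter / (len(a) + len(b))
    jac = 1.0 if not union else inter / union
    return acc, dsc, jac


def ahd_oracle(pred, gt):
    """All-pairs brute force of the symmetric average Hausdorff distance."""
    p = np.argwhere(pred).astype(float)
    g = np.argwhere(gt).astype(float)
    d = cdist(g, p)
    return (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0


def auc_oracle(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------- frozen toy examples

def test_confusion_counts_on_enumerated_3x3_grid():
    gt = np.zeros((3, 3), dtype=int)
    gt[0, 0] = gt[0, 1] = gt[1, 0] = 1
    pred = np.zeros((3, 3), dtype=int)
    for r, c in [(0, 0), (0, 1), (2, 2), (2, 1), (1, 1)]:
        pred[r, c] = 1
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 3, 1, 3)


@pytest.mark.parametrize("counts,expected", [
    (ConfusionCounts(2, 5, 2, 1), 0.7),
    (ConfusionCounts(3, 0, 0, 0), 1.0),
    (ConfusionCounts(0, 0, 2, 3), 0.0),
])
def test_accuracy_examples(counts, expected):
    assert accuracy(counts) == pytest.approx(expected)


def test_dice_and_iou_examples():
    c = ConfusionCounts(tp=3, tn=0, fp=1, fn=1)
    assert dice(c) == pytest.approx(0.75)
    assert iou(c) == pytest.approx(0.6)
    assert dice(ConfusionCounts(0, 9, 2, 3)) == 0.0
    # empty-vs-empty convention
    assert dice(ConfusionCounts(0, 9, 0, 0)) == 1.0
    assert iou(ConfusionCounts(0, 9, 0, 0)) == 1.0


def test_avg_hausdorff_hand_computed_cases():
    a = np.zeros((6, 6), dtype=int)
    b = np.zeros((6, 6), dtype=int)
    a[0, 0] = 1
    b[3, 4] = 1
    assert avg_hausdorff(a, b) == pytest.approx(5.0)
    gt = np.zeros((4, 4), dtype=int)
    gt[0, 0] = gt[0, 2] = 1
    pred = np.zeros((4, 4), dtype=int)
    pred[0, 0] = 1
    # (mean(0, 2) + mean(0)) / 2
    assert avg_hausdorff(pred, gt) == pytest.approx(0.5)
    assert avg_hausdorff(gt, gt) == 0.0


def test_roc_auc_four_pixel_example():
    scores = np.array([0.9, 0.4, 0.6, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(scores, labels) == pytest.approx(0.75)
    assert roc_auc(np.full(4, 0.5), labels) == pytest.approx(0.5)


# ---------------------------------------------------------------- properties

def test_overlap_metrics_match_oracles_on_random_masks(rng):
    for _ in range(60):
        shape = (int(rng.integers(1, 33)), int(rng.integers(1, 33)))
        pred = rng.random(shape) < rng.uniform(0.05, 0.6)
        gt = rng.random(shape) < rng.uniform(0.05, 0.6)
        c = confusion_counts(pred, gt)
        o_acc, o_dsc, o_iou = overlap_oracle(pred, gt)
        assert accuracy(c) == pytest.approx(o_acc, abs=1e-10)
        assert dice(c) == pytest.approx(o_dsc, abs=1e-10)
        assert iou(c) == pytest.approx(o_iou, abs=1e-10)
        # algebraic identity and ordering
        assert dice(c) == pytest.approx(2 * iou(c) / (1 + iou(c)), abs=1e-10)
        assert dice(c) >= iou(c)
        if pred.any() and gt.any():
            assert avg_hausdorff(pred, gt) == pytest.approx(
                ahd_oracle(pred, gt), abs=1e-10)


def test_avg_hausdorff_symmetry_and_zero_iff_equal(rng):
    a = rng.random((12, 12)) < 0.3
    b = rng.random((12, 12)) < 0.3
    a[0, 0] = b[1, 1] = True  # ensure non-empty
    assert avg_hausdorff(a, b) == pytest.approx(avg_hausdorff(b, a), abs=1e-12)
    assert avg_hausdorff(a, a) == 0.0
    if not np.array_equal(a, b):
        assert avg_hausdorff(a, b) > 0


def test_roc_auc_matches_exhaustive_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(25):
        n = int(rng.integers(4, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        mine = roc_auc(scores, labels)
        assert mine == pytest.approx(auc_oracle(scores, labels), abs=1e-10)
        assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)
        # negation symmetry
        assert roc_auc(-scores, labels) == pytest.approx(1.0 - mine, abs=1e-10)


def test_permutation_invariance_of_count_metrics(rng):
    pred = rng.random((8, 8)) < 0.4
    gt = rng.random((8, 8)) < 0.4
    perm = rng.permutation(64)
    c1 = confusion_counts(pred, gt)
    c2 = confusion_counts(pred.ravel()[perm].reshape(8, 8),
                          gt.ravel()[perm].reshape(8, 8))
    assert (c1.tp, c1.tn, c1.fp, c1.fn) == (c2.tp, c2.tn, c2.fp, c2.fn)


# ------------------------------------------------------------------- errors

def test_degenerate_inputs_are_signalled():
    with pytest.raises(PairingError):
        confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))
    with pytest.raises(UndefinedMetricError):
        avg_hausdorff(np.zeros((4, 4), int), np.ones((4, 4), int))
    with pytest.raises(UndefinedMetricError):
        roc_auc(np.random.rand(9), np.ones(9, dtype=bool))


def test_evaluate_pair_flags_undefined_distance():
    empty = np.zeros((4, 4), int)
    rep = evaluate_pair(empty, empty)
    assert rep.acc == 1.0 and rep.dsc == 1.0 and rep.iou == 1.0
    assert rep.avgdist is None
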