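"""Segmentation evaluation: pixel accuracy, Dice, IoU, average Hausdorff
distance, and ROC-AUC.

All overlap metrics derive from per-pixel confusion counts between a binary
prediction and its ground truth:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    DSC = 2·TP / (FP + 2·TP + FN)
    IoU =   TP / (FP +   TP + FN)

with the algebraic identity DSC = 2·IoU / (1 + IoU).  The average Hausdorff
distance is the symmetric mean of directed average nearest-neighbour
Euclidean distances between the two foreground point sets, in pixels.
ROC-AUC uses the rank (Mann–Whitney) formulation: the probability that a
random foreground pixel outscores a random background pixel, ties counted
half.

Conventions for degenerate inputs: with both masks empty, ACC = DSC = IoU
= 1 (perfect agreement on all-background); the average Hausdorff distance
is undefined whenever either mask is empty, and AUC is undefined when the
ground truth has only one class — both raise :class:`UndefinedMetricError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .ct_io import MaskSlice
from .errors import PairingError, UndefinedMetricError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "accuracy",
           "dice", "iou", "avg_hausdorff", "roc_auc", "evaluate_pair",
           "evaluate_batch"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    dsc: float
    iou: float
    avgdist: float | None   # None when undefined (an empty mask)
    auc: float | None = None


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, MaskSlice):
        return mask.pixels.astype(bool)
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1, True, False)).all():
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Per-pixel TP/TN/FP/FN tally between two binary masks."""
    p = _as_bool(pred)
    g = _as_bool(gt)
    if p.shape != g.shape:
        raise PairingError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int((p & g).sum())
    tn = int((~p & ~g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero pixels")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        return 1.0  # both masks empty: treat as perfect agreement
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.fp + c.tp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def _foreground_points(mask, boundary: bool):
    m = _as_bool(mask)
    if boundary and m.any():
        from scipy.ndimage import binary_erosion
        m = m & ~binary_erosion(m)
    return np.argwhere(m).astype(np.float64)


def avg_hausdorff(pred, gt, boundary: bool = False) -> float:
    """Symmetric average Hausdorff distance between foreground point sets.

    With ``boundary=True`` only boundary pixels (foreground minus its
    erosion) enter the computation.
    """
    pp = _foreground_points(pred, boundary)
    gp = _foreground_points(gt, boundary)
    if len(pp) == 0 or len(gp) == 0:
        raise UndefinedMetricError(
            "average Hausdorff distance undefined for an empty mask "
            f"(pred {len(pp)} pts, gt {len(gp)} pts)")
    tree_p = cKDTree(pp)
    tree_g = cKDTree(gp)
    g_to_p = tree_p.query(gp, k=1)[0].mean()
    p_to_g = tree_g.query(pp, k=1)[0].mean()
    return float((g_to_p + p_to_g) / 2.0)


def roc_auc(prob_map, gt) -> float:
    """Rank-based (Mann–Whitney) AUC of a probability map against a mask."""
    g = _as_bool(gt).ravel()
    s = np.asarray(prob_map, dtype=np.float64).ravel()
    if s.shape != g.shape:
        raise PairingError("probability map and mask sizes differ")
    n1 = int(g.sum())
    n0 = g.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined: ground truth has one class")
    ranks = rankdata(s)  # average ranks => ties counted half
    return float((ranks[g].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate_pair(pred, gt, prob_map=None, boundary: bool = False) -> MetricsReport:
    """All four mask metrics (plus AUC when a probability map is supplied).

    `avgdist` is None when either mask is empty; `auc` is None when no
    probability map is given or the ground truth has a single class.
    """
    c = confusion_counts(pred, gt)
    try:
        ahd = avg_hausdorff(pred, gt, boundary=boundary)
    except UndefinedMetricError:
        ahd = None
    auc = None
    if prob_map is not None:
        try:
            auc = roc_auc(prob_map, gt)
        except UndefinedMetricError:
            auc = None
    return MetricsReport(accuracy(c), dice(c), iou(c), ahd, auc)


def evaluate_batch(pred_gt_pairs, ids=None):
    """Per-pair metric rows plus a mean summary row, as a DataFrame."""
    import pandas as pd

    rows = []
    for i, (pred, gt) in enumerate(pred_gt_pairs):
        r = evaluate_pair(pred, gt)
        rows.append(dict(slice_id=ids[i] if ids else f"pair{i:05d}",
                         ACC=r.acc, DSC=r.dsc, IoU=r.iou,
                         AVGDIST=math.nan if r.avgdist is None else r.avgdist))
    df = pd.DataFrame(rows)
    mean = df[["ACC", "DSC", "IoU", "AVGDIST"]].mean(skipna=True)
    df.loc[len(df)] = dict(slice_id="mean", **mean.to_dict())
    return df
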