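"""Compound IoU + Dice training objective.

With soft counts TP = Σ p·t, FP = Σ p·(1−t), FN = Σ (1−p)·t over per-voxel
foreground probabilities p and a binary target t:

    L_IoU  = 1 − (TP + ε) / (TP + FP + FN + ε)
    L_Dice = 1 − (2·TP + ε) / (2·TP + FP + FN + ε)
    L      = (L_IoU + L_Dice) / 2

The smoothing ε (1e-5) keeps the empty-target/empty-prediction case finite
and equal to 0.  The same code path accepts plain NumPy arrays (returning a
float) or autodiff tensors from :mod:`avmseg.nn` (returning a differentiable
scalar), so the evaluation-time and training-time losses cannot drift apart.
Because Dice ≥ IoU for any counts, L_Dice ≤ L_IoU and the compound loss lies
between them.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

EPS = 1e-5


def _validate(pred, target):
    pshape = pred.shape
    tshape = np.asarray(target).shape if not isinstance(target, Tensor) \
        else target.shape
    if pshape != tshape:
        raise ValueError(f"shape mismatch: pred {pshape} vs target {tshape}")
    if not isinstance(pred, Tensor):
        p = np.asarray(pred)
        if p.size and (p.min() < -1e-6 or p.max() > 1 + 1e-6):
            raise ValueError("prediction probabilities must lie in [0, 1]")


def _soft_counts(pred, target):
    t = np.asarray(target, dtype=np.float32) if not isinstance(target, Tensor) \
        else target
    tp = (pred * t).sum()
    fp = (pred * (1.0 - t)).sum()
    fn = ((1.0 - pred) * t).sum()
    return tp, fp, fn


def iou_loss(pred, target, eps: float = EPS):
    """1 − IoU with soft counts; in [0, 1]."""
    _validate(pred, target)
    tp, fp, fn = _soft_counts(pred, target)
    return 1.0 - (tp + eps) / (tp + fp + fn + eps)


def dice_loss(pred, target, eps: float = EPS):
    """1 − Dice with soft counts; in [0, 1]."""
    _validate(pred, target)
    tp, fp, fn = _soft_counts(pred, target)
    return 1.0 - (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)


def composite_loss(pred, target, eps: float = EPS):
    """Mean of the IoU and Dice losses — the training objective."""
    return (iou_loss(pred, target, eps) + dice_loss(pred, target, eps)) * 0.5


# Hard-count forms, useful for closed-form checks and reporting -------------

def iou_loss_from_counts(tp: float, fp: float, fn: float,
                         eps: float = EPS) -> float:
    return 1.0 - (tp + eps) / (tp + fp + fn + eps)


def dice_loss_from_counts(tp: float, fp: float, fn: float,
                          eps: float = EPS) -> float:
    return 1.0 - (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)


def composite_loss_from_counts(tp: float, fp: float, fn: float,
                               eps: float = EPS) -> float:
    return 0.5 * (iou_loss_from_counts(tp, fp, fn, eps)
                  + dice_loss_from_counts(tp, fp, fn, eps))
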