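"""Training objectives: masked MAE, the DVH criteria loss, and the cascade total.

The coarse model is trained with mean absolute error over the possible-dose
mask (``V_p`` voxels); the refinement model with the DVH loss — the mean
absolute difference between the ``D_1..D_99`` criteria vectors of the true
and predicted doses over the ``n_p`` criteria the patient possesses.  The
cascade total is ``0.5 * MAE(A) + L_DVH(B)``: the coarse head is an auxiliary
output, so it carries half weight.

Each loss comes with its analytic gradient with respect to the prediction.
The percentile in the DVH loss is linear interpolation between two order
statistics, so its gradient is sparse: for each criterion it touches at most
the two voxels that define the interpolated percentile, with the
interpolation weights (ties resolved by stable sort order).  The losses are
therefore piecewise differentiable, which is exactly what lets the network
train through them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np

from .errors import DomainError
from .patient_io import STRUCTURE_NAMES

__all__ = [
    "LossBreakdown",
    "mae_loss",
    "mae_loss_grad",
    "dvh_loss",
    "dvh_loss_grad",
    "total_loss",
]


@dataclass(frozen=True)
class LossBreakdown:
    """Components of the cascade objective, all in Gy."""

    mae_a: float
    dvh_b: float

    @property
    def total(self) -> float:
        return 0.5 * self.mae_a + self.dvh_b


def mae_loss(pred: np.ndarray, true: np.ndarray, possible_mask: np.ndarray) -> float:
    """Mean absolute error over the possible-dose mask."""
    return mae_loss_grad(pred, true, possible_mask)[0]


def mae_loss_grad(pred: np.ndarray, true: np.ndarray,
                  possible_mask: np.ndarray) -> Tuple[float, np.ndarray]:
    """(value, d value / d pred).  Voxels outside the mask contribute nothing."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    mask = np.asarray(possible_mask)
    if pred.shape != true.shape or pred.shape != mask.shape:
        raise DomainError("pred, true and mask must share one grid")
    v_p = int((mask > 0).sum())
    if v_p == 0:
        raise DomainError("possible-dose mask is empty")
    diff = np.where(mask > 0, pred - true, 0.0)
    value = float(np.abs(diff).sum() / v_p)
    grad = np.sign(diff) / v_p
    return value, grad


def _criteria_and_grad(values: np.ndarray, need_grad: bool):
    """D_1..D_99 of a 1-D dose vector and, per criterion, the (index, weight)
    pairs of the <=2 order statistics that define it."""
    n = values.size
    order = np.argsort(values, kind="stable")
    svals = values[order]
    ks = np.arange(1, 100)
    ranks = (100.0 - ks) / 100.0 * (n - 1)
    lo = np.floor(ranks).astype(np.int64)
    hi = np.minimum(lo + 1, n - 1)
    w = ranks - lo
    qs = svals[lo] * (1.0 - w) + svals[hi] * w
    if not need_grad:
        return qs, None
    return qs, (order[lo], order[hi], w)


def dvh_loss(pred: np.ndarray, true: np.ndarray,
             masks: Mapping[str, np.ndarray]) -> float:
    return dvh_loss_grad(pred, true, masks)[0]


def dvh_loss_grad(pred: np.ndarray, true: np.ndarray,
                  masks: Mapping[str, np.ndarray]) -> Tuple[float, np.ndarray]:
    """(L_DVH, gradient w.r.t. pred).

    Mean absolute difference of the criteria vectors over all ``n_p``
    criteria of the present structures.  The gradient flows only to the mask
    voxels selected by the percentile interpolation.
    """
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    present = [n for n in STRUCTURE_NAMES if n in masks]
    if not present:
        raise DomainError("DVH loss undefined: no structures present")
    n_p = 99 * len(present)
    total = 0.0
    grad = np.zeros_like(pred)
    flat_grad = grad.reshape(-1)
    for name in present:
        mask = np.asarray(masks[name])
        if mask.shape != pred.shape:
            raise DomainError(f"mask {name} shape mismatch")
        idx = np.flatnonzero(mask.reshape(-1))
        if idx.size == 0:
            raise DomainError(f"structure {name} has zero voxels")
        pv = pred.reshape(-1)[idx]
        tv = true.reshape(-1)[idx]
        q_pred, (ilo, ihi, w) = _criteria_and_grad(pv, need_grad=True)
        q_true, _ = _criteria_and_grad(tv, need_grad=False)
        delta = q_pred - q_true
        total += float(np.abs(delta).sum())
        sgn = np.sign(delta) / n_p
        np.add.at(flat_grad, idx[ilo], sgn * (1.0 - w))
        np.add.at(flat_grad, idx[ihi], sgn * w)
    return total / n_p, grad


def total_loss(pred_a: np.ndarray, pred_b: np.ndarray, true: np.ndarray,
               masks: Mapping[str, np.ndarray],
               possible_mask: np.ndarray) -> LossBreakdown:
    """Cascade objective: ``0.5 * MAE(pred_a) + L_DVH(pred_b)``."""
    mae_a = mae_loss(pred_a, true, possible_mask)
    dvh_b = dvh_loss(pred_b, true, masks)
    return LossBreakdown(mae_a=mae_a, dvh_b=dvh_b)
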