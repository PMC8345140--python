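"""Segmentation losses: BCE, soft-Dice, soft-IoU, focal, Lovász hinge.

Every component maps a foreground logit map and a binary target to a
non-negative scalar plus its gradient w.r.t. the logits; ``compute_loss``
evaluates a weighted sum of named components.  Soft-Dice and soft-IoU are
``1 - (soft overlap ratio)``; focal uses the customary gamma=2, alpha=0.25;
the Lovász hinge is the convex surrogate of the Jaccard loss evaluated on
the foreground logit, with the gradient taken through the sorted-error
weights held fixed (the standard practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossSpec", "compute_loss", "LOSS_COMPONENTS"]

_EPS = 1e-7


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray):
    """Mean binary cross-entropy; numerically stable log-sum-exp form."""
    n = z.size
    # log(1 + e^{-|z|}) + max(z,0) - z*t
    loss = float(np.mean(np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0) - z * t))
    grad = (_sigmoid(z) - t) / n
    return loss, grad


def soft_dice_loss(z: np.ndarray, t: np.ndarray):
    p = _sigmoid(z)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + _EPS
    dice = (2.0 * inter + _EPS) / denom
    # d dice / d p = (2*t*denom - (2*inter+eps)) / denom^2
    ddice_dp = (2.0 * t * denom - (2.0 * inter + _EPS)) / denom**2
    grad = -ddice_dp * p * (1.0 - p)
    return 1.0 - dice, grad


def soft_iou_loss(z: np.ndarray, t: np.ndarray):
    p = _sigmoid(z)
    inter = float((p * t).sum())
    union = float(p.sum() + t.sum()) - inter + _EPS
    iou = (inter + _EPS) / union
    diou_dp = (t * union - (inter + _EPS) * (1.0 - t)) / union**2
    grad = -diou_dp * p * (1.0 - p)
    return 1.0 - iou, grad


def focal_loss(z: np.ndarray, t: np.ndarray, gamma: float = 2.0,
               alpha: float = 0.25):
    p = _sigmoid(z)
    pt = np.where(t > 0.5, p, 1.0 - p)
    at = np.where(t > 0.5, alpha, 1.0 - alpha)
    logpt = np.log(np.clip(pt, _EPS, 1.0))
    n = z.size
    loss = float(np.mean(-at * (1.0 - pt) ** gamma * logpt))
    # dloss/dpt, then chain through pt -> p -> z
    dl_dpt = -at * ((1.0 - pt) ** gamma / np.clip(pt, _EPS, 1.0)
                    - gamma * (1.0 - pt) ** (gamma - 1.0) * logpt)
    sign = np.where(t > 0.5, 1.0, -1.0)
    grad = dl_dpt * sign * p * (1.0 - p) / n
    return loss, grad


def _lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard loss w.r.t. sorted errors."""
    gts = gt_sorted.sum()
    if gts == 0:
        return np.zeros_like(gt_sorted, dtype=np.float64)
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    out = jaccard.copy()
    out[1:] = jaccard[1:] - jaccard[:-1]
    return out


def lovasz_hinge(z: np.ndarray, t: np.ndarray):
    zf = z.ravel().astype(np.float64)
    tf = t.ravel().astype(np.float64)
    signs = 2.0 * tf - 1.0
    errors = 1.0 - zf * signs
    order = np.argsort(-errors, kind="stable")
    errors_sorted = errors[order]
    g = _lovasz_grad(tf[order])
    relu = np.maximum(errors_sorted, 0.0)
    loss = float(relu @ g)
    grad_sorted = np.where(errors_sorted > 0, g, 0.0) * (-signs[order])
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad.reshape(z.shape).astype(z.dtype)


LOSS_COMPONENTS = {
    "bce": bce_with_logits,
    "dice": soft_dice_loss,
    "iou": soft_iou_loss,
    "focal": focal_loss,
    "lovasz": lovasz_hinge,
}


@dataclass(frozen=True)
class LossSpec:
    """A weighted combination of loss components.

    ``components`` is a subset of {bce, dice, iou, focal, lovasz}; weights
    default to 1.0 each (combination losses in the training sweeps are plain
    unweighted sums, e.g. BCE+IoU).
    """

    components: tuple[str, ...] = ("bce",)
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("loss spec needs at least one component")
        names = [c.lower() for c in self.components]
        unknown = [c for c in names if c not in LOSS_COMPONENTS]
        if unknown:
            raise ValueError(f"unknown loss components: {unknown}")
        object.__setattr__(self, "components", tuple(names))
        w = self.weights if self.weights is not None else (1.0,) * len(names)
        if len(w) != len(names):
            raise ValueError("one weight per component required")
        if any(wi <= 0 for wi in w):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "weights", tuple(float(wi) for wi in w))

    @classmethod
    def parse(cls, text: str) -> "LossSpec":
        """Parse 'bce+iou' style strings."""
        return cls(components=tuple(p.strip() for p in text.split("+")))


def compute_loss(pred: np.ndarray, target: np.ndarray, spec: LossSpec,
                 with_grad: bool = False, from_logits: bool = False):
    """Weighted sum of the spec's components on one batch.

    ``pred`` holds foreground probabilities in (0, 1) (clipped away from the
    endpoints), or pre-sigmoid logits when ``from_logits`` is set — the form
    the training loop uses, since gradients flow w.r.t. logits.  Returns
    ``loss`` or ``(loss, grad_wrt_logits)``; raises on NaN input.
    """
    pred = np.asarray(pred)
    if from_logits:
        logits = pred
    else:
        if np.isnan(pred).any():
            raise ValueError("NaN in loss inputs")
        p = np.clip(pred, _EPS, 1.0 - _EPS)
        logits = np.log(p) - np.log1p(-p)
    target = np.asarray(target, dtype=logits.dtype)
    if logits.shape != target.shape:
        raise ValueError("logits and target shapes differ")
    if np.isnan(logits).any() or np.isnan(target).any():
        raise ValueError("NaN in loss inputs")
    total = 0.0
    grad = np.zeros_like(logits) if with_grad else None
    for name, w in zip(spec.components, spec.weights):
        value, g = LOSS_COMPONENTS[name](logits, target)
        total += w * value
        if with_grad:
            grad += w * g
    if with_grad:
        return total, grad
    return total
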