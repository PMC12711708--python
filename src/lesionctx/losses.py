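"""Composite multi-task loss and the cosine learning-rate schedule.

L_total = lambda_seg * L_seg + lambda_cls * L_cls + lambda_reg * L_reg, with
L_seg = 1 - Dice + alpha * L_focal (Dice = 2|P.G| / (|P| + |G|) on soft
masks; focal alpha 0.25, gamma 2.0), L_cls a class-weighted binary
cross-entropy with weights (1.8, 2.3, 1.6) for (pneumothorax, hemorrhage,
pleural reaction), and L_reg an L2 weight penalty (1e-4) plus a multi-scale
prediction-consistency term. Mixing weights default to
(lambda_seg, lambda_cls, lambda_reg) = (1.0, 0.5, 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PROB_CLAMP = 1e-7


@dataclass
class LossConfig:
    lambda_seg: float = 1.0
    lambda_cls: float = 0.5
    lambda_reg: float = 0.1
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    #: mixing weight of the focal term inside L_seg (exposed separately from
    #: the focal alpha; both default to 0.25)
    seg_focal_mix: float = 0.25
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "pneumothorax": 1.8,
            "hemorrhage": 2.3,
            "pleural_reaction": 1.6,
        }
    )
    l2_coefficient: float = 1e-4

    def __post_init__(self) -> None:
        vals = [
            self.lambda_seg, self.lambda_cls, self.lambda_reg,
            self.focal_alpha, self.focal_gamma, self.seg_focal_mix,
            self.l2_coefficient, *self.class_weights.values(),
        ]
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


def soft_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice = 2|P.G| / (|P| + |G|) on soft masks."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and ground-truth shapes differ")
    num = 2.0 * float((pred * truth).sum())
    den = float(pred.sum() + truth.sum())
    return num / den if den > 0 else 1.0


def focal_loss(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean focal loss -alpha (1 - p_t)^gamma log(p_t); p_t is the predicted
    probability of the true class."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and ground-truth shapes differ")
    p = _clamp(np.asarray(pred, dtype=float))
    t = np.asarray(truth, dtype=float)
    p_t = np.where(t > 0.5, p, 1.0 - p)
    return float(np.mean(-alpha * (1.0 - p_t) ** gamma * np.log(p_t)))


def weighted_bce(
    pred_probs: dict[str, float], labels: dict[str, int], class_weights: dict[str, float]
) -> float:
    """L_cls = -sum_i w_i [y_i log(y^_i) + (1 - y_i) log(1 - y^_i)]."""
    total = 0.0
    for risk, w in class_weights.items():
        if risk not in pred_probs or risk not in labels:
            raise ValueError(f"missing prediction or label for task '{risk}'")
        p = float(np.clip(pred_probs[risk], PROB_CLAMP, 1.0 - PROB_CLAMP))
        y = float(labels[risk])
        total += -w * (y * math.log(p) + (1.0 - y) * math.log(1.0 - p))
    return total


def consistency_loss(multiscale_preds: list[np.ndarray]) -> float:
    """Mean-squared disagreement between decoder-level soft segmentations,
    each downsampled to the coarsest common grid."""
    if len(multiscale_preds) < 2:
        return 0.0
    target_shape = multiscale_preds[-1].shape
    resampled = []
    for p in multiscale_preds:
        factors = tuple(s // t for s, t in zip(p.shape, target_shape))
        q = p
        for ax, f in enumerate(factors):
            if f > 1:
                q = np.add.reduceat(q, np.arange(0, q.shape[ax], f), axis=ax) / f
        resampled.append(q)
    base = resampled[0]
    return float(np.mean([np.mean((r - base) ** 2) for r in resampled[1:]]))


def l2_penalty(parameters: list[np.ndarray]) -> float:
    return float(sum(np.sum(np.square(p)) for p in parameters))


def composite_loss(
    pred_mask: np.ndarray | None,
    true_mask: np.ndarray | None,
    pred_probs: dict[str, float],
    labels: dict[str, int],
    config: LossConfig | None = None,
    parameters: list[np.ndarray] | None = None,
    multiscale_preds: list[np.ndarray] | None = None,
) -> dict[str, float]:
    """Total loss and its components; total is exactly the weighted sum."""
    config = config or LossConfig()
    if pred_mask is not None and true_mask is not None:
        l_seg = (
            1.0
            - soft_dice(pred_mask, true_mask)
            + config.seg_focal_mix * focal_loss(pred_mask, true_mask, config.focal_alpha, config.focal_gamma)
        )
    else:
        l_seg = 0.0
    l_cls = weighted_bce(pred_probs, labels, config.class_weights)
    l_reg = config.l2_coefficient * l2_penalty(parameters or [])
    if multiscale_preds:
        l_reg += consistency_loss(multiscale_preds)
    total = config.lambda_seg * l_seg + config.lambda_cls * l_cls + config.lambda_reg * l_reg
    return {"total": total, "seg": l_seg, "cls": l_cls, "reg": l_reg}


def cosine_lr(t: float, lr_min: float, lr_max: float, t_max: float) -> float:
    """LR(t) = LR_min + (LR_max - LR_min) (1 + cos(pi t / T_max)) / 2."""
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    return lr_min + (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / t_max)) / 2.0
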