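"""Training objective (BCE + Dice) and the six segmentation metrics.

The training loss is L = 0.5 * BCE(y_hat, y) + (1 - softDice(y_hat, y)); the
cross-entropy is computed from logits for numerical stability and the Dice
term uses additive smoothing eps = 1 in numerator and denominator. The
evaluation metrics (IoU, Dice, sensitivity, accuracy, positive predictive
value, specificity) are pixel-level ratios of confusion counts; each image is
scored from its own counts and a set is summarized by the per-image mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import engine
from .nn.engine import Tensor, as_tensor

DICE_SMOOTH = 1.0
METRIC_NAMES = ("IoU", "Dice", "SE", "Acc", "PPV", "SP")


def _check_binary(y: np.ndarray) -> None:
    if not np.isin(y, (0, 1)).all():
        raise ValueError("target mask must be strictly binary (0/1)")


def soft_dice_loss(probs: Tensor, targets: np.ndarray,
                   smooth: float = DICE_SMOOTH) -> Tensor:
    """1 - (2 * sum(p*y) + eps) / (sum(p) + sum(y) + eps)."""
    probs = as_tensor(probs)
    y = np.asarray(targets, dtype=probs.dtype)
    inter = engine.tsum(engine.mul(probs, y))
    denom = engine.add(engine.tsum(probs), float(y.sum()))
    dice = engine.div(engine.add(engine.mul(inter, 2.0), smooth),
                      engine.add(denom, smooth))
    return engine.add(engine.mul(dice, -1.0), 1.0)


def bce_dice_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Combined objective 0.5*BCE + DiceLoss, from logits."""
    logits = as_tensor(logits)
    y = np.asarray(targets)
    if logits.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {y.shape}")
    _check_binary(y)
    bce = engine.bce_with_logits_mean(logits, y)
    dice = soft_dice_loss(engine.sigmoid(logits), y)
    return engine.add(engine.mul(bce, 0.5), dice)


def bce_dice_loss_from_probs(probs: np.ndarray, targets: np.ndarray,
                             clip: float = 1e-7) -> float:
    """Loss evaluated from probabilities (clipped), for worked examples and
    checking predictions that are already squashed."""
    p = np.clip(np.asarray(probs, dtype=np.float64), clip, 1 - clip)
    y = np.asarray(targets, dtype=np.float64)
    _check_binary(y)
    bce = float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())
    inter = float((p * y).sum())
    dice = 1.0 - (2 * inter + DICE_SMOOTH) / (p.sum() + y.sum() + DICE_SMOOTH)
    return 0.5 * bce + dice


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities; a value equal to the threshold is foreground."""
    return (np.asarray(probs) >= threshold).astype(np.uint8)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion tallies between two binary masks."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    _check_binary(pred)
    _check_binary(gt)
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(tp=int((p & g).sum()), fp=int((p & ~g).sum()),
                           fn=int((~p & g).sum()), tn=int((~p & ~g).sum()))


def _ratio(num: int, den: int) -> float:
    # Vacuous agreement: an empty denominator (e.g. empty ground truth and
    # empty prediction for SE) scores 1 rather than crashing.
    return num / den if den > 0 else 1.0


def segmentation_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """IoU, Dice, SE (sensitivity), Acc, PPV (precision), SP (specificity)."""
    return {
        "IoU": _ratio(cc.tp, cc.fp + cc.tp + cc.fn),
        "Dice": _ratio(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn),
        "SE": _ratio(cc.tp, cc.tp + cc.fn),
        "Acc": _ratio(cc.tp + cc.tn, cc.total),
        "PPV": _ratio(cc.tp, cc.tp + cc.fp),
        "SP": _ratio(cc.tn, cc.tn + cc.fp),
    }


def metrics_table(rows: list[dict[str, float]], identifiers: list[str]) -> pd.DataFrame:
    """Per-image metric rows plus a final per-image-mean row labelled 'mean'."""
    df = pd.DataFrame(rows, index=identifiers, columns=list(METRIC_NAMES))
    df.index.name = "image"
    df.loc["mean"] = df.mean(axis=0)
    return df
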