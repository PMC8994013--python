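"""Training losses: focal classification, smooth-L1 regression, mask BCE.

Focal loss FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t) with p_t the
probability assigned to an anchor's true class (p for positives, 1-p for
background); ignored anchors contribute nothing and the sum is normalized
by the positive-anchor count.  The smooth-L1 regression loss uses the
sigma-breakpoint form F(x) = 0.5*x^2/sigma for |x| < sigma, |x| - 0.5*sigma
otherwise (quadratic near zero, linear in the tails).  The segmentation
branch uses average binary cross-entropy over mask pixels.

These are the reference numpy implementations; the training graph
re-expresses them with autodiff ops and is unit-checked against this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from echoseg.anchors import POSITIVE, BACKGROUND

EPS = 1e-7

__all__ = ["FocalParams", "SmoothL1Params", "focal_loss", "smooth_l1",
           "mask_bce", "total_loss", "EPS"]


@dataclass(frozen=True)
class FocalParams:
    alpha_t: float = 0.25
    gamma: float = 2.0

    def validate(self) -> None:
        if not (0 < self.alpha_t <= 1):
            raise ValueError("alpha_t must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class SmoothL1Params:
    sigma: float = 3.0

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def focal_loss(true_labels: np.ndarray, pred_probs: np.ndarray,
               params: FocalParams = FocalParams()) -> float:
    """Focal classification loss over anchors, normalized by positive count.

    ``true_labels`` uses the anchor label convention (1 positive,
    0 background, -1 ignore); ``pred_probs`` are foreground probabilities.
    """
    params.validate()
    labels = np.asarray(true_labels).ravel()
    p = np.clip(np.asarray(pred_probs, dtype=float).ravel(), EPS, 1 - EPS)
    if labels.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    pt = np.where(labels == POSITIVE, p, 1.0 - p)
    fl = -params.alpha_t * (1.0 - pt) ** params.gamma * np.log(pt)
    fl = np.where((labels == POSITIVE) | (labels == BACKGROUND), fl, 0.0)
    n_pos = max(1, int(np.sum(labels == POSITIVE)))
    return float(fl.sum() / n_pos)


def smooth_l1(residuals: np.ndarray,
              params: SmoothL1Params = SmoothL1Params()) -> float:
    """Mean smooth-L1 over regression residuals; 0 when there are none."""
    params.validate()
    x = np.asarray(residuals, dtype=float).ravel()
    if x.size == 0:
        return 0.0
    ax = np.abs(x)
    f = np.where(ax < params.sigma, 0.5 * x * x / params.sigma,
                 ax - 0.5 * params.sigma)
    return float(f.mean())


def mask_bce(gt_mask: np.ndarray, pred_mask_probs: np.ndarray) -> float:
    """Average binary cross-entropy over mask pixels."""
    y = np.asarray(gt_mask, dtype=float)
    p = np.asarray(pred_mask_probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"mask shape {y.shape} != prediction shape {p.shape}")
    p = np.clip(p, EPS, 1 - EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def total_loss(cls: float, reg: float, mask: float,
               weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Weighted sum of the three branch losses."""
    wc, wr, wm = weights
    return float(wc * cls + wr * reg + wm * mask)
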