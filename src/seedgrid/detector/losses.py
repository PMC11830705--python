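"""Bounding-box containers and IoU-family regression losses.

Implements the Complete-IoU (CIoU) loss and the Wise-IoU family (v1 and the
dynamic non-monotonic v3), the two box-regression losses compared for seed
detection.  Boxes are axis-aligned, stored center-size ``(cx, cy, w, h)`` in
whatever frame the caller states (normalized tile coordinates for labels,
tray pixels after globalization).

Loss conventions: the plain IoU loss is ``L_IoU = 1 - IoU``.  CIoU adds a
normalized center-distance term and an aspect-ratio consistency term
``v = (4/pi^2)(arctan(w/h) - arctan(w_gt/h_gt))^2`` weighted by
``alpha = v / (L_IoU + v)``.  Wise-IoU v1 rescales ``L_IoU`` by
``R_WIoU = exp(rho^2 / (Wg^2 + Hg^2))`` with the enclosing-box diagonal
treated as a constant; v3 further multiplies by a non-monotonic focusing
coefficient ``r = beta / (delta * alpha^(beta - delta))`` of the outlier
degree ``beta`` — the current detached ``L_IoU`` over its running mean — so
gradient gain concentrates on medium-quality anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from ..errors import ConfigError, DataError


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in center-size form; ``frame`` names the units."""

    cx: float
    cy: float
    w: float
    h: float
    frame: str = "tile"

    def __post_init__(self):
        if self.w < 0 or self.h < 0:
            raise DataError(f"box with negative size: w={self.w}, h={self.h}")

    @property
    def x_lo(self) -> float:
        return self.cx - self.w / 2

    @property
    def x_hi(self) -> float:
        return self.cx + self.w / 2

    @property
    def y_lo(self) -> float:
        return self.cy - self.h / 2

    @property
    def y_hi(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corners(cls, x_lo, y_lo, x_hi, y_hi, frame="tile") -> "BBox":
        return cls(
            cx=(x_lo + x_hi) / 2,
            cy=(y_lo + y_hi) / 2,
            w=x_hi - x_lo,
            h=y_hi - y_lo,
            frame=frame,
        )

    def union_with(self, other: "BBox") -> "BBox":
        return BBox.from_corners(
            min(self.x_lo, other.x_lo),
            min(self.y_lo, other.y_lo),
            max(self.x_hi, other.x_hi),
            max(self.y_hi, other.y_hi),
            frame=self.frame,
        )


@dataclass(frozen=True)
class Detection:
    """A detected seed: box, confidence, and (optionally) its source tile."""

    bbox: BBox
    confidence: float = 1.0
    class_id: int = 0
    source_tile: tuple[int, int] | None = None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise DataError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class LossState:
    """Running state of the Wise-IoU v3 focusing mechanism.

    ``running_mean_iou_loss`` is the exponential moving average of detached
    ``1 - IoU`` values; ``alpha``/``delta`` are the focusing hyperparameters
    (1.9 and 3 in the seed-detection setting).
    """

    running_mean_iou_loss: float = 1.0
    momentum: float = 0.9
    alpha: float = 1.9
    delta: float = 3.0

    def __post_init__(self):
        if self.alpha <= 1:
            raise ConfigError("alpha must be > 1")
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if not 0.0 < self.momentum < 1.0:
            raise ConfigError("momentum must lie in (0, 1)")


def _check_sized(*boxes: BBox):
    for b in boxes:
        if b.w <= 0 or b.h <= 0:
            raise DataError("zero-sized box")


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 1 iff identical, 0 iff disjoint."""
    wi = min(a.x_hi, b.x_hi) - max(a.x_lo, b.x_lo)
    hi = min(a.y_hi, b.y_hi) - max(a.y_lo, b.y_lo)
    if wi <= 0 or hi <= 0:
        return 0.0
    inter = wi * hi
    # areas from the same corner arithmetic, so identical boxes give exactly 1
    area_a = (a.x_hi - a.x_lo) * (a.y_hi - a.y_lo)
    area_b = (b.x_hi - b.x_lo) * (b.y_hi - b.y_lo)
    return inter / (area_a + area_b - inter)


def _enclosing_diag_sq(a: BBox, b: BBox) -> float:
    wg = max(a.x_hi, b.x_hi) - min(a.x_lo, b.x_lo)
    hg = max(a.y_hi, b.y_hi) - min(a.y_lo, b.y_lo)
    return wg * wg + hg * hg


def ciou_loss(pred: BBox, gt: BBox) -> float:
    """Complete-IoU loss: overlap + center distance + aspect-ratio terms."""
    _check_sized(pred, gt)
    l_iou = 1.0 - iou(pred, gt)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    diag2 = _enclosing_diag_sq(pred, gt)
    v = (4.0 / math.pi**2) * (
        math.atan(pred.w / pred.h) - math.atan(gt.w / gt.h)
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / (l_iou + v)
    return l_iou + rho2 / diag2 + alpha * v


def wiou_v1(pred: BBox, gt: BBox) -> float:
    """Wise-IoU v1: IoU loss scaled by the detached center-distance factor."""
    _check_sized(pred, gt)
    l_iou = 1.0 - iou(pred, gt)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    r_wiou = math.exp(rho2 / _enclosing_diag_sq(pred, gt))
    return r_wiou * l_iou


def wiou_v3_factor(beta: float, alpha: float = 1.9, delta: float = 3.0) -> float:
    """Non-monotonic focusing coefficient ``r = beta / (delta * alpha^(beta - delta))``.

    ``r(delta) = 1`` exactly; ``r -> 0`` both as ``beta -> 0`` and as
    ``beta -> inf``, so extreme-quality anchors get small gradient gain.
    """
    if beta < 0:
        raise ConfigError("outlier degree beta must be >= 0")
    return beta / (delta * alpha ** (beta - delta))


def wiou_v3(pred: BBox, gt: BBox, state: LossState) -> tuple[float, LossState]:
    """Wise-IoU v3 loss and the updated running-mean state.

    The outlier degree ``beta`` is the current detached ``1 - IoU`` over the
    running mean; the loss is ``r(beta) * wiou_v1``.  The running mean is
    then updated by an exponential moving average with ``state.momentum``.
    """
    if state.running_mean_iou_loss is None or state.running_mean_iou_loss <= 0:
        raise ConfigError(
            "uninitialized loss state: warm up the running mean "
            "(e.g. LossState(running_mean_iou_loss=1.0)) before wiou_v3"
        )
    _check_sized(pred, gt)
    l_iou = 1.0 - iou(pred, gt)
    beta = l_iou / state.running_mean_iou_loss
    loss = wiou_v3_factor(beta, state.alpha, state.delta) * wiou_v1(pred, gt)
    new_mean = state.momentum * state.running_mean_iou_loss + (1 - state.momentum) * l_iou
    return loss, replace(state, running_mean_iou_loss=new_mean)
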