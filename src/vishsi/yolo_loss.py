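"""Composite single-stage detection loss with scale-dependent objectness gain.

The loss over a batch of N matched positive samples is

    L = (1/N) Σ [ w_cls · L_cls + α(scale) · L_obj + w_box · L_box ]

with default weights w_cls = 0.5 and w_box = 0.05.  L_cls is cross-entropy
between the true and predicted class distributions; L_box is 1 − CIoU
(complete IoU: IoU minus a normalised centre-distance penalty and an
aspect-ratio consistency penalty); L_obj is binary cross-entropy between the
predicted objectness and the prediction–truth IoU.  α is piecewise constant
in the ground-truth box area with a small : medium : large gain ratio of
4 : 1 : 0.4 (area thresholds default to the conventional 32² and 96² px²).

This is a standalone, analytically testable computation — no network, no
training loop.  The positive-sample assignment rule (centre in the cell or
one of the two adjacent cells, width/height ratio within 4×) is exposed as a
predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossConfig",
    "PredictionTarget",
    "ciou",
    "classification_loss",
    "objectness_loss",
    "scale_gain",
    "composite_loss",
    "is_positive_assignment",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Weights and scale-gain schedule for the composite loss."""

    w_cls: float = 0.5
    w_box: float = 0.05
    obj_gain_base: float = 1.0
    gain_ratio: tuple[float, float, float] = (4.0, 1.0, 0.4)
    scale_thresholds: tuple[float, float] = (32.0**2, 96.0**2)

    def __post_init__(self) -> None:
        if min(self.w_cls, self.w_box, self.obj_gain_base) <= 0:
            raise ValueError("loss weights must be positive")
        if min(self.gain_ratio) <= 0 or len(self.gain_ratio) != 3:
            raise ValueError("gain ratio needs three positive entries")
        lo, hi = self.scale_thresholds
        if not 0 < lo < hi:
            raise ValueError("scale thresholds must be increasing and positive")


def _corners(box) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = (float(v) for v in box)
    if not (x0 < x1 and y0 < y1):
        raise ValueError("degenerate box")
    return x0, y0, x1, y1


def _iou_corners(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = min(ax1, bx1) - max(ax0, bx0)
    iy = min(ay1, by1) - max(ay0, by0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def ciou(pred, truth) -> float:
    """Complete-IoU loss, 1 − CIoU ∈ [0, 2].

    CIoU = IoU − ρ²/c² − α·v, with ρ the centre distance, c the diagonal of
    the smallest enclosing box, v = (4/π²)(Δ arctan aspect)², and
    α = v / ((1 − IoU) + v).  Zero iff the boxes coincide.
    """
    p, t = _corners(pred), _corners(truth)
    iou_val = _iou_corners(p, t)
    pcx, pcy = (p[0] + p[2]) / 2, (p[1] + p[3]) / 2
    tcx, tcy = (t[0] + t[2]) / 2, (t[1] + t[3]) / 2
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    ex0, ey0 = min(p[0], t[0]), min(p[1], t[1])
    ex1, ey1 = max(p[2], t[2]), max(p[3], t[3])
    c2 = (ex1 - ex0) ** 2 + (ey1 - ey0) ** 2
    pw, ph = p[2] - p[0], p[3] - p[1]
    tw, th = t[2] - t[0], t[3] - t[1]
    v = (4 / np.pi**2) * (np.arctan(tw / th) - np.arctan(pw / ph)) ** 2
    alpha = 0.0 if v == 0 else v / ((1 - iou_val) + v)
    return float(1 - (iou_val - rho2 / c2 - alpha * v))


def classification_loss(p_gt, p_c) -> float:
    """Cross-entropy −Σ p_gt · log(p_c), with logits clamped for safety."""
    p_gt = np.asarray(p_gt, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    if p_gt.shape != p_c.shape:
        raise ValueError("distribution shapes differ")
    if p_gt.min() < 0 or p_c.min() < -1e-12 or p_c.max() > 1 + 1e-12:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(-np.sum(p_gt * np.log(np.clip(p_c, _EPS, 1.0))))


def objectness_loss(objectness: float, target_iou: float) -> float:
    """Binary cross-entropy between predicted objectness and the match IoU."""
    if not 0 <= objectness <= 1 or not 0 <= target_iou <= 1:
        raise ValueError("objectness and IoU must lie in [0, 1]")
    o = np.clip(objectness, _EPS, 1 - _EPS)
    return float(-(target_iou * np.log(o) + (1 - target_iou) * np.log(1 - o)))


def scale_gain(truth_area: float, cfg: LossConfig = LossConfig()) -> float:
    """Piecewise-constant objectness gain α by ground-truth box area."""
    if truth_area <= 0:
        raise ValueError("box area must be positive")
    small, medium, large = cfg.gain_ratio
    lo, hi = cfg.scale_thresholds
    if truth_area < lo:
        r = small
    elif truth_area <= hi:
        r = medium
    else:
        r = large
    return cfg.obj_gain_base * r


@dataclass(frozen=True)
class PredictionTarget:
    """One matched positive sample: predicted box vs its ground truth.

    Boxes are (x_min, y_min, x_max, y_max); class distributions are aligned
    vectors; ``objectness`` is the predicted confidence in [0, 1].
    """

    pred_box: tuple[float, float, float, float]
    truth_box: tuple[float, float, float, float]
    p_gt: tuple[float, ...]
    p_c: tuple[float, ...]
    objectness: float = 1.0

    def __post_init__(self) -> None:
        _corners(self.pred_box)
        _corners(self.truth_box)
        if not 0 <= self.objectness <= 1:
            raise ValueError("objectness must lie in [0, 1]")

    @property
    def truth_area(self) -> float:
        x0, y0, x1, y1 = self.truth_box
        return (x1 - x0) * (y1 - y0)


def composite_loss(batch, cfg: LossConfig = LossConfig()) -> float:
    """Mean composite loss over a batch of matched positive samples."""
    batch = list(batch)
    if not batch:
        raise ValueError("empty batch")
    total = 0.0
    for s in batch:
        l_cls = classification_loss(s.p_gt, s.p_c)
        match_iou = _iou_corners(_corners(s.pred_box), _corners(s.truth_box))
        l_obj = objectness_loss(s.objectness, match_iou)
        l_box = ciou(s.pred_box, s.truth_box)
        alpha = scale_gain(s.truth_area, cfg)
        total += cfg.w_cls * l_cls + alpha * l_obj + cfg.w_box * l_box
    return total / len(batch)


def is_positive_assignment(
    pred_wh: tuple[float, float],
    anchor_wh: tuple[float, float],
    center_offset: tuple[float, float],
    max_ratio: float = 4.0,
) -> bool:
    """Positive-sample predicate: size ratio within ``max_ratio`` and centre
    within the cell or one of the two adjacent cells (offset in (−0.5, 1.5)).
    """
    pw, ph = pred_wh
    aw, ah = anchor_wh
    if min(pw, ph, aw, ah) <= 0:
        raise ValueError("box sizes must be positive")
    ratio = max(pw / aw, aw / pw, ph / ah, ah / ph)
    ox, oy = center_offset
    return ratio < max_ratio and -0.5 < ox < 1.5 and -0.5 < oy < 1.5
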