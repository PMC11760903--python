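"""Bounding-box regression losses: IoU, CIoU and SIoU.

CIoU penalizes plain IoU with the normalized squared center distance and an
aspect-ratio consistency term ``v`` weighted by ``alpha``.  Its known
weakness is that ``v`` vanishes whenever the predicted and ground-truth
aspect ratios agree, even if the sizes are very different, which destabilizes
convergence.  SIoU replaces the penalty with three geometric costs:

* **angle cost** ``Lambda`` — how far the line joining the two box centers
  is from an axis (0 on-axis, 1 at 45 degrees);
* **distance cost** ``Delta`` — center offsets normalized by the enclosing
  box, with the exponent rate ``gamma = 2 - Lambda`` so that off-axis pairs
  are penalized less steeply;
* **shape cost** ``Omega`` — relative width/height mismatch raised to an
  exponent ``theta`` that controls how much shape is emphasized.

The total SIoU loss is ``1 - IoU + (Delta + Omega) / 2``.  Unlike CIoU's
``v``, ``Omega`` stays positive whenever sizes differ, including the
equal-aspect-ratio case.

All losses are exposed both as scalar calls returning an auditable
:class:`LossBreakdown` and as a batched call that also runs on
:class:`~algadet.autodiff.Tensor` inputs inside a training graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .boxes import Box, EnclosureGeometry, InvalidBoxError, as_box_array, validate_boxes

__all__ = [
    "DEFAULT_THETA",
    "THETA_ADMISSIBLE",
    "LossBreakdown",
    "InvalidGeometryError",
    "iou",
    "ciou_loss",
    "siou_loss",
    "siou_angle_cost",
    "siou_distance_cost",
    "siou_shape_cost",
    "batched_loss",
    "batched_breakdown",
]

#: default shape-cost exponent and the admissible range accepted without warning
DEFAULT_THETA = 4.0
THETA_ADMISSIBLE = (2.0, 6.0)

_TINY = 1e-300  # guards exact-zero denominators without distorting finite values


class InvalidGeometryError(ValueError):
    """Raised when an enclosure geometry is internally inconsistent."""


@dataclass(frozen=True)
class LossBreakdown:
    """Loss value plus every intermediate the formulas produce.

    ``angle_cost``/``distance_cost``/``shape_cost`` are the SIoU components
    (zero for IoU/CIoU calls); ``ciou_penalty_v``/``ciou_alpha`` are the
    CIoU aspect term and its balance weight (zero for IoU/SIoU calls).
    """

    iou: float
    angle_cost: float
    distance_cost: float
    shape_cost: float
    ciou_penalty_v: float
    ciou_alpha: float
    loss: float


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if theta <= 0:
        raise ValueError(f"shape-cost exponent theta must be positive, got {theta}")
    return theta


def _split(b):
    """Split (N, 4) array/Tensor into cx, cy, w, h columns."""
    return b[:, 0], b[:, 1], b[:, 2], b[:, 3]


def _corners(cx, cy, w, h):
    return cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5


def _iou_core(pred, gt):
    pcx, pcy, pw, ph = _split(pred)
    gcx, gcy, gw, gh = _split(gt)
    px1, py1, px2, py2 = _corners(pcx, pcy, pw, ph)
    gx1, gy1, gx2, gy2 = _corners(gcx, gcy, gw, gh)
    iw = ad.maximum(ad.minimum(px2, gx2) - ad.maximum(px1, gx1), 0.0)
    ih = ad.maximum(ad.minimum(py2, gy2) - ad.maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    # clamp absorbs one-ulp overshoot from the union subtraction
    return ad.clip(inter / union, 0.0, 1.0)


def _enclosure_core(pred, gt):
    pcx, pcy, pw, ph = _split(pred)
    gcx, gcy, gw, gh = _split(gt)
    px1, py1, px2, py2 = _corners(pcx, pcy, pw, ph)
    gx1, gy1, gx2, gy2 = _corners(gcx, gcy, gw, gh)
    ew = ad.maximum(px2, gx2) - ad.minimum(px1, gx1)
    eh = ad.maximum(py2, gy2) - ad.minimum(py1, gy1)
    dx = gcx - pcx
    dy = gcy - pcy
    return ew, eh, dx, dy


def _angle_core(dx, dy):
    """Angle cost Lambda for signed center offsets.

    Written as 2*|dx|*|dy|/sigma^2, algebraically identical to
    1 - 2*sin^2(arcsin(|dy|/sigma) - pi/4) but smooth for gradients and
    exactly 0 when the centers coincide or are axis-aligned.
    """
    sig2 = dx * dx + dy * dy
    lam = 2.0 * ad.absolute(dx) * ad.absolute(dy) / ad.maximum(sig2, _TINY)
    return ad.clip(lam, 0.0, 1.0)


def _siou_core(pred, gt, theta: float):
    iou_v = _iou_core(pred, gt)
    ew, eh, dx, dy = _enclosure_core(pred, gt)
    lam = _angle_core(dx, dy)
    gamma = 2.0 - lam
    rho_x = (dx / ew) ** 2.0
    rho_y = (dy / eh) ** 2.0
    delta = (1.0 - ad.exp(-gamma * rho_x)) + (1.0 - ad.exp(-gamma * rho_y))
    pw, ph = pred[:, 2], pred[:, 3]
    gw, gh = gt[:, 2], gt[:, 3]
    w_w = ad.absolute(pw - gw) / ad.maximum(pw, gw)
    w_h = ad.absolute(ph - gh) / ad.maximum(ph, gh)
    omega = (1.0 - ad.exp(-w_w)) ** theta + (1.0 - ad.exp(-w_h)) ** theta
    loss = 1.0 - iou_v + (delta + omega) * 0.5
    return iou_v, lam, delta, omega, loss


def _ciou_core(pred, gt):
    iou_v = _iou_core(pred, gt)
    ew, eh, dx, dy = _enclosure_core(pred, gt)
    rho2 = dx * dx + dy * dy
    c2 = ew * ew + eh * eh
    pw, ph = pred[:, 2], pred[:, 3]
    gw, gh = gt[:, 2], gt[:, 3]
    v = (4.0 / math.pi**2) * (ad.arctan(gw / gh) - ad.arctan(pw / ph)) ** 2.0
    # alpha is treated as a constant weight (no gradient), and defined as 0
    # at the optimum where (1 - IoU) + v = 0
    denom = (1.0 - ad.detach(iou_v)) + ad.detach(v)
    alpha = np.where(denom > 0, ad.detach(v) / np.maximum(denom, _TINY), 0.0)
    loss = 1.0 - iou_v + rho2 / c2 + alpha * v
    return iou_v, v, alpha, loss


# ---------------------------------------------------------------------------
# scalar API


def iou(a, b) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    pa = as_box_array(a).reshape(1, 4)
    pb = as_box_array(b).reshape(1, 4)
    validate_boxes(pa)
    validate_boxes(pb)
    return float(_iou_core(pa, pb)[0])


def siou_angle_cost(geom: EnclosureGeometry) -> float:
    """Angle cost Lambda in [0, 1] from an enclosure geometry.

    Lambda = 1 - 2 sin^2(arcsin(center_dy / sigma) - pi/4); 0 when the two
    centers are axis-aligned (or coincide, by convention), 1 when the line
    joining them is at exactly 45 degrees.
    """
    sigma = geom.center_dist
    if sigma < 0:
        raise InvalidGeometryError("center distance must be non-negative")
    if sigma == 0:
        return 0.0
    ratio = geom.center_dy / sigma
    if ratio > 1.0 + 1e-9:
        raise InvalidGeometryError(
            f"center_dy ({geom.center_dy}) exceeds center distance ({sigma})"
        )
    ratio = min(max(ratio, 0.0), 1.0)
    lam = 1.0 - 2.0 * math.sin(math.asin(ratio) - math.pi / 4.0) ** 2
    return min(max(lam, 0.0), 1.0)


def siou_distance_cost(geom: EnclosureGeometry, angle_cost: float) -> float:
    """Distance cost Delta in [0, 2) given the angle cost Lambda.

    Delta = sum_t (1 - exp(-gamma * rho_t)) with gamma = 2 - Lambda and
    rho_x/rho_y the squared center offsets normalized by the enclosure.
    """
    if not (geom.enclose_w > 0 and geom.enclose_h > 0):
        raise InvalidGeometryError("enclosure must have positive extent")
    if not 0.0 <= angle_cost <= 1.0:
        raise InvalidGeometryError(f"angle cost must lie in [0, 1], got {angle_cost}")
    gamma = 2.0 - angle_cost
    rho_x = (geom.center_dx / geom.enclose_w) ** 2
    rho_y = (geom.center_dy / geom.enclose_h) ** 2
    return (1.0 - math.exp(-gamma * rho_x)) + (1.0 - math.exp(-gamma * rho_y))


def siou_shape_cost(pred, gt, theta: float = DEFAULT_THETA) -> float:
    """Shape cost Omega in [0, 2): relative w/h mismatch to the power theta."""
    theta = _check_theta(theta)
    p = as_box_array(pred).reshape(4)
    g = as_box_array(gt).reshape(4)
    validate_boxes(p.reshape(1, 4))
    validate_boxes(g.reshape(1, 4))
    w_w = abs(p[2] - g[2]) / max(p[2], g[2])
    w_h = abs(p[3] - g[3]) / max(p[3], g[3])
    return (1.0 - math.exp(-w_w)) ** theta + (1.0 - math.exp(-w_h)) ** theta


def ciou_loss(pred, gt) -> LossBreakdown:
    """CIoU loss of a box pair: 1 - IoU + rho^2/c^2 + alpha * v."""
    p = as_box_array(pred).reshape(1, 4)
    g = as_box_array(gt).reshape(1, 4)
    validate_boxes(p)
    validate_boxes(g)
    iou_v, v, alpha, loss = _ciou_core(p, g)
    return LossBreakdown(
        iou=float(iou_v[0]),
        angle_cost=0.0,
        distance_cost=0.0,
        shape_cost=0.0,
        ciou_penalty_v=float(v[0]),
        ciou_alpha=float(alpha[0]),
        loss=float(loss[0]),
    )


def siou_loss(pred, gt, theta: float = DEFAULT_THETA) -> LossBreakdown:
    """SIoU loss of a box pair: 1 - IoU + (Delta + Omega) / 2."""
    theta = _check_theta(theta)
    p = as_box_array(pred).reshape(1, 4)
    g = as_box_array(gt).reshape(1, 4)
    validate_boxes(p)
    validate_boxes(g)
    iou_v, lam, delta, omega, loss = _siou_core(p, g, theta)
    return LossBreakdown(
        iou=float(iou_v[0]),
        angle_cost=float(lam[0]),
        distance_cost=float(delta[0]),
        shape_cost=float(omega[0]),
        ciou_penalty_v=0.0,
        ciou_alpha=0.0,
        loss=float(loss[0]),
    )


# ---------------------------------------------------------------------------
# batched API


def _as_batch(boxes):
    if ad.is_tensor(boxes):
        if boxes.ndim != 2 or boxes.shape[1] != 4:
            raise ValueError(f"expected shape (N, 4), got {boxes.shape}")
        return boxes
    if hasattr(boxes, "__len__") and len(boxes) == 0:
        return np.zeros((0, 4))
    arr = as_box_array(boxes)
    if arr.size == 0:
        return arr.reshape(0, 4)
    arr = arr.reshape(-1, 4)
    validate_boxes(arr)
    return arr


def batched_loss(preds, gts, kind: str = "siou", reduction: str = "mean",
                 theta: float = DEFAULT_THETA):
    """Element-wise box loss over equal-length batches.

    Parameters
    ----------
    preds, gts : (N, 4) array-like, sequence of Box, or Tensor
        Predicted and ground-truth boxes in center format.
    kind : {"iou", "ciou", "siou"}
        ``"iou"`` means the loss ``1 - IoU``.
    reduction : {"none", "mean", "sum"}
    theta : float
        SIoU shape-cost exponent (ignored for other kinds).

    Returns the per-pair loss vector (``reduction="none"``) or the reduced
    scalar.  When either input is an autodiff Tensor the result is a Tensor
    and gradients flow to the predicted coordinates.
    """
    p = _as_batch(preds)
    g = _as_batch(gts)
    if p.shape[0] != g.shape[0]:
        raise ValueError(f"length mismatch: {p.shape[0]} predictions vs {g.shape[0]} ground truths")
    if kind not in ("iou", "ciou", "siou"):
        raise ValueError(f"unknown loss kind {kind!r}")
    if reduction not in ("none", "mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if p.shape[0] == 0:
        empty = np.zeros(0)
        if reduction == "none":
            return empty
        return 0.0

    if kind == "iou":
        per = 1.0 - _iou_core(p, g)
    elif kind == "ciou":
        per = _ciou_core(p, g)[3]
    else:
        per = _siou_core(p, g, _check_theta(theta))[4]

    if reduction == "none":
        return per
    if reduction == "sum":
        return ad.tsum(per)
    return ad.tmean(per)


def batched_breakdown(preds, gts, kind: str = "siou", theta: float = DEFAULT_THETA):
    """Vector LossBreakdown over a batch (plain arrays only)."""
    p = _as_batch(preds)
    g = _as_batch(gts)
    if p.shape[0] != g.shape[0]:
        raise ValueError("length mismatch between predictions and ground truths")
    n = p.shape[0]
    zeros = np.zeros(n)
    if kind == "siou":
        iou_v, lam, delta, omega, loss = _siou_core(p, g, _check_theta(theta))
        return LossBreakdown(iou=iou_v, angle_cost=lam, distance_cost=delta,
                             shape_cost=omega, ciou_penalty_v=zeros,
                             ciou_alpha=zeros, loss=loss)
    if kind == "ciou":
        iou_v, v, alpha, loss = _ciou_core(p, g)
        return LossBreakdown(iou=iou_v, angle_cost=zeros, distance_cost=zeros,
                             shape_cost=zeros, ciou_penalty_v=v,
                             ciou_alpha=alpha, loss=loss)
    if kind == "iou":
        iou_v = _iou_core(p, g)
        return LossBreakdown(iou=iou_v, angle_cost=zeros, distance_cost=zeros,
                             shape_cost=zeros, ciou_penalty_v=zeros,
                             ciou_alpha=zeros, loss=1.0 - iou_v)
    raise ValueError(f"unknown loss kind {kind!r}")
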