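"""Independent scalar oracles for the box-loss formulas.

Straight-line transcriptions using only the ``math`` module, kept separate
from the package's vectorized implementation so the two can be compared as
independent routes to the same numbers.
"""

import math


def iou_scalar(pred, gt):
    pcx, pcy, pw, ph = pred
    gcx, gcy, gw, gh = gt
    px1, py1, px2, py2 = pcx - pw / 2, pcy - ph / 2, pcx + pw / 2, pcy + ph / 2
    gx1, gy1, gx2, gy2 = gcx - gw / 2, gcy - gh / 2, gcx + gw / 2, gcy + gh / 2
    iw = max(0.0, min(px2, gx2) - max(px1, gx1))
    ih = max(0.0, min(py2, gy2) - max(py1, gy1))
    inter = iw * ih
    return inter / (pw * ph + gw * gh - inter)


def ciou_scalar(pred, gt):
    """CIoU loss: 1 - IoU + rho^2/c^2 + alpha*v."""
    pcx, pcy, pw, ph = pred
    gcx, gcy, gw, gh = gt
    overlap = iou_scalar(pred, gt)
    ew = max(pcx + pw / 2, gcx + gw / 2) - min(pcx - pw / 2, gcx - gw / 2)
    eh = max(pcy + ph / 2, gcy + gh / 2) - min(pcy - ph / 2, gcy - gh / 2)
    rho2 = (gcx - pcx) ** 2 + (gcy - pcy) ** 2
    c2 = ew**2 + eh**2
    v = (4.0 / math.pi**2) * (math.atan(gw / gh) - math.atan(pw / ph)) ** 2
    denom = (1.0 - overlap) + v
    alpha = v / denom if denom > 0 else 0.0
    return 1.0 - overlap + rho2 / c2 + alpha * v


def siou_scalar(pred, gt, theta=4.0):
    """SIoU loss: 1 - IoU + (Delta + Omega)/2, angle cost via arcsin."""
    pcx, pcy, pw, ph = pred
    gcx, gcy, gw, gh = gt
    overlap = iou_scalar(pred, gt)
    ew = max(pcx + pw / 2, gcx + gw / 2) - min(pcx - pw / 2, gcx - gw / 2)
    eh = max(pcy + ph / 2, gcy + gh / 2) - min(pcy - ph / 2, gcy - gh / 2)
    dx = abs(gcx - pcx)
    dy = abs(gcy - pcy)
    sigma = math.hypot(dx, dy)
    if sigma == 0:
        lam = 0.0
    else:
        ratio = min(max(dy / sigma, 0.0), 1.0)
        lam = 1.0 - 2.0 * math.sin(math.asin(ratio) - math.pi / 4.0) ** 2
        lam = min(max(lam, 0.0), 1.0)
    gamma = 2.0 - lam
    rho_x = ((gcx - pcx) / ew) ** 2
    rho_y = ((gcy - pcy) / eh) ** 2
    delta = (1.0 - math.exp(-gamma * rho_x)) + (1.0 - math.exp(-gamma * rho_y))
    w_w = abs(pw - gw) / max(pw, gw)
    w_h = abs(ph - gh) / max(ph, gh)
    omega = (1.0 - math.exp(-w_w)) ** theta + (1.0 - math.exp(-w_h)) ** theta
    return 1.0 - overlap + (delta + omega) / 2.0


def random_box_pairs(rng, n):
    """Seeded random valid box pairs covering overlap and disjoint cases."""
    pairs = []
    for _ in range(n):
        p = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(0.1, 6), rng.uniform(0.1, 6))
        g = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(0.1, 6), rng.uniform(0.1, 6))
        pairs.append((p, g))
    return pairs
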