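"""A tiny single-scale reference detector for desk-scale experiments.

This is deliberately the smallest architecture that exercises the box
losses and the CAGS block end to end — one stride, one anchor per grid
cell, fixed local-patch features and a learnable 1x1-convolution head — not
a replica of any full-scale detector.  It exists so that loss functions,
attention and the evaluator can be integrated, trained and measured on a
laptop-scale synthetic dataset in minutes.

Pipeline per image:

1. fixed feature extraction: the image is divided into a ``G x G`` grid
   (``G = image_size / stride``); each cell is described by block-mean
   intensities of a fine patch (localization cues) plus radial ring
   statistics of a wider window (rotation-invariant morphology cues),
   standardized with a per-channel scaler fitted on the training set;
2. optional CAGS attention over the ``[C, G, G]`` feature map;
3. a learnable pointwise head mapping each cell to
   ``(objectness, tx, ty, tw, th, class logits)``;
4. YOLO-style decoding: the center offset uses the extended range
   ``2*sigmoid - 0.5`` cells and width/height scale a fixed anchor
   exponentially.

Because the training budget of a desk-scale run is a few dozen SGD steps,
``fit`` first solves the head in closed form (ridge regression in the
attention-gated feature space) and then refines everything — attention
block included — with the actual detection losses: objectness binary
cross-entropy over all cells, softmax cross-entropy and the configured box
regression loss (SIoU or CIoU) on object-covered cells.

The estimator follows scikit-learn conventions: ``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .boxes import Box
from .cags import CAGS, CagsConfig
from .losses import DEFAULT_THETA, batched_loss
from .losses import iou as box_iou
from .metrics import DetectionRecord, EvalResult, mean_ap
from .nn import SGD, Adam, PointwiseConv
from .synthetic import load_image, read_yolo_labels

__all__ = ["TrainConfig", "TinyDetector", "encode_offsets", "decode_offsets", "smoke_train"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the standard single-GPU recipe for full-scale detector
    training (learning rate 0.01, momentum 0.937, weight decay 0.0005,
    batch 16, 640x640 input); :meth:`smoke` overrides to the desk-scale
    regime this package actually trains at.
    """

    learning_rate: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch_size: int = 16
    epochs: int = 120
    image_size: int = 640
    loss_kind: str = "siou"
    use_cags: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs, self.image_size) <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.loss_kind not in ("iou", "ciou", "siou"):
            raise ValueError(f"unknown loss kind {self.loss_kind!r}")

    @classmethod
    def smoke(cls, loss_kind: str = "siou", use_cags: bool = True, seed: int = 0) -> "TrainConfig":
        """Toy-scale settings: 128px images, batch 4, 5 epochs, and a small
        refinement learning rate (the head starts from a closed-form
        ridge solution, so the epochs polish rather than fit from
        scratch)."""
        return cls(
            learning_rate=0.005,
            momentum=0.9,
            weight_decay=0.0005,
            batch_size=4,
            epochs=5,
            image_size=128,
            loss_kind=loss_kind,
            use_cags=use_cags,
            seed=seed,
        )


def decode_offsets(t: np.ndarray, cell_row: int, cell_col: int, stride: int,
                   anchor: float, image_size: int) -> Box:
    """(tx, ty, tw, th) at a grid cell -> normalized center-format Box.

    The center offset uses the extended range ``2*sigmoid(t) - 0.5`` (from
    -0.5 to +1.5 cells), so a cell adjacent to an object center can still
    regress onto it; width/height scale the anchor exponentially.
    """
    tx, ty, tw, th = (float(v) for v in t)
    sx = 2.0 / (1.0 + np.exp(-tx)) - 0.5
    sy = 2.0 / (1.0 + np.exp(-ty)) - 0.5
    cx = (cell_col + sx) * stride / image_size
    cy = (cell_row + sy) * stride / image_size
    w = anchor / image_size * np.exp(tw)
    h = anchor / image_size * np.exp(th)
    return Box(cx, cy, w, h)


def encode_offsets(box: Box, cell_row: int, cell_col: int, stride: int,
                   anchor: float, image_size: int) -> np.ndarray:
    """Inverse of :func:`decode_offsets` (logit of the scaled cell offset)."""
    fx = (box.cx * image_size / stride - cell_col + 0.5) / 2.0
    fy = (box.cy * image_size / stride - cell_row + 0.5) / 2.0
    eps = 1e-7
    fx, fy = np.clip(fx, eps, 1 - eps), np.clip(fy, eps, 1 - eps)
    return np.array([
        np.log(fx / (1 - fx)),
        np.log(fy / (1 - fy)),
        np.log(box.w * image_size / anchor),
        np.log(box.h * image_size / anchor),
    ])


def _weighted_bce_with_logits(z, targets: np.ndarray, weights: np.ndarray):
    """Numerically stable binary cross-entropy with per-element weights.

    Zero weight drops an element entirely (ignore regions around object
    centers); positives carry the imbalance-correction weight.  Normalized
    by the number of contributing elements."""
    per = ad.maximum(z, 0.0) - z * targets + ad.log(1.0 + ad.exp(-ad.absolute(z)))
    n = max(int(np.count_nonzero(weights)), 1)
    return ad.tsum(per * weights) * (1.0 / n)


def _nms(records: list[DetectionRecord], iou_threshold: float) -> list[DetectionRecord]:
    """Class-agnostic non-maximum suppression.

    Agnostic (rather than per-class) suppression matters at this scale: a
    neighboring grid cell firing on the same object often disagrees about
    the class, and per-class NMS would let that duplicate through as a
    high-ranked false positive.
    """
    kept: list[DetectionRecord] = []
    for rec in sorted(records, key=lambda r: -r.score):
        if all(box_iou(rec.box, k.box) < iou_threshold for k in kept):
            kept.append(rec)
    return kept


class TinyDetector:
    """Scikit-learn-style estimator wrapping the tiny detector.

    Parameters
    ----------
    image_size : int
        Input side length; must be divisible by `stride`.
    stride : int
        Grid cell size in pixels (one anchor per cell).
    n_classes : int
        Number of object classes.
    anchor_scale : float
        Anchor side length in units of the stride.
    learning_rate, momentum, weight_decay, batch_size, epochs : float/int
        Optimization settings for the refinement epochs.
    loss_kind : {"iou", "ciou", "siou"}
        Box regression loss.
    use_cags : bool
        Insert a CAGS attention block before the head.
    theta : float
        SIoU shape-cost exponent.
    box_weight : float
        Weight of the box loss relative to the classification terms.
    obj_pos_weight : float
        Up-weighting of positive cells in the objectness loss (dense-grid
        imbalance correction).
    optimizer : {"adam", "sgd"}
        Refinement optimizer; `momentum` applies to "sgd" only.
    conf_threshold, nms_iou : float
        Prediction-time score floor and class-agnostic NMS threshold.
    seed : int
        Controls parameter initialization and batch shuffling.

    Attributes (after ``fit``)
    --------------------------
    head_, cags_ : learnable modules (``cags_`` is None when disabled)
    feature_mean_, feature_std_ : per-channel feature scaler
    history_ : list of per-epoch loss dictionaries
    """

    _PATCH_GRID = 6  # fine block-mean patch per cell (localization cues)
    _RING_BINS = 6  # radial rings over a wide window (rotation-invariant class cues)

    def __init__(self, image_size: int = 128, stride: int = 8, n_classes: int = 7,
                 anchor_scale: float = 4.0, learning_rate: float = 0.005,
                 momentum: float = 0.9, weight_decay: float = 0.0005,
                 batch_size: int = 4, epochs: int = 5, loss_kind: str = "siou",
                 use_cags: bool = True, theta: float = DEFAULT_THETA,
                 box_weight: float = 2.0, obj_pos_weight: float = 16.0,
                 optimizer: str = "adam", conf_threshold: float = 0.05,
                 nms_iou: float = 0.5, seed: int = 0):
        self.image_size = image_size
        self.stride = stride
        self.n_classes = n_classes
        self.anchor_scale = anchor_scale
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.loss_kind = loss_kind
        self.use_cags = use_cags
        self.theta = theta
        self.box_weight = box_weight
        self.obj_pos_weight = obj_pos_weight
        self.optimizer = optimizer
        self.conf_threshold = conf_threshold
        self.nms_iou = nms_iou
        self.seed = seed

    # -- sklearn protocol --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        names = list(inspect.signature(type(self).__init__).parameters)[1:]
        return {n: getattr(self, n) for n in names}

    def set_params(self, **params) -> "TinyDetector":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for TinyDetector")
            setattr(self, k, v)
        return self

    # -- features ----------------------------------------------------------
    def _grid_size(self) -> int:
        if self.image_size % self.stride != 0:
            raise ValueError(
                f"image_size ({self.image_size}) must be divisible by stride ({self.stride})"
            )
        return self.image_size // self.stride

    @property
    def _n_feature_channels(self) -> int:
        return self._PATCH_GRID**2 + 2 * self._RING_BINS + 3 + 7

    def _features(self, image: np.ndarray) -> np.ndarray:
        """Fixed per-cell features, shape [C, G, G].

        Three complementary descriptor families per grid cell: block-mean
        intensities of a fine patch around the cell center (orientation
        cues for center-offset and size regression); radial ring mean/std
        profiles over a wider window plus window-level statistics; and
        darkness-weighted second-moment shape statistics (total mass,
        spread, elongation, dark-pixel fraction).  The latter two families
        are rotation-invariant morphology cues for classification — the
        cell shapes appear at arbitrary orientation, so raw patches alone
        generalize poorly for the class head, and elongation separates
        otherwise radially similar morphologies (spindles and flagellated
        ellipses from discs and eggs).
        """
        s, g, q = self.stride, self._grid_size(), self._PATCH_GRID
        if image.shape != (self.image_size, self.image_size):
            raise ValueError(
                f"expected {self.image_size}x{self.image_size} image, got {image.shape}"
            )
        # fine block-mean patch, 3-stride window
        win = 3 * s
        block = max(win // q, 1)
        win = block * q
        pad = win // 2
        padded = np.pad(image, pad, mode="edge")
        integral = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
        integral[1:, 1:] = padded.cumsum(0).cumsum(1)
        # window top-left (in padded coords) for cell (i, j): i*s + s/2 + pad - win/2
        base = np.arange(g) * s + s // 2 + pad - win // 2
        feats = np.empty((self._n_feature_channels, g, g))
        for bi in range(q):
            y0 = base + bi * block
            for bj in range(q):
                x0 = base + bj * block
                y0g, x0g = np.meshgrid(y0, x0, indexing="ij")
                tot = (
                    integral[y0g + block, x0g + block]
                    - integral[y0g, x0g + block]
                    - integral[y0g + block, x0g]
                    + integral[y0g, x0g]
                )
                feats[bi * q + bj] = tot / block**2
        # radial ring profiles, 6-stride window
        nr = self._RING_BINS
        rwin = 6 * s
        rpad = rwin // 2
        rpadded = np.pad(image, rpad, mode="edge")
        yy, xx = np.mgrid[0:rwin, 0:rwin] - (rwin - 1) / 2.0
        radius = np.hypot(yy, xx)
        edges = np.linspace(0, rwin / 2.0, nr + 1)
        ring_masks = [(radius >= edges[k]) & (radius < edges[k + 1]) for k in range(nr)]
        off = q * q
        moff = off + 2 * nr + 3
        for i in range(g):
            cy = i * s + s // 2 + rpad
            for j in range(g):
                cx = j * s + s // 2 + rpad
                window = rpadded[cy - rpad : cy + rpad, cx - rpad : cx + rpad]
                for k, mask in enumerate(ring_masks):
                    vals = window[mask]
                    feats[off + 2 * k, i, j] = vals.mean()
                    feats[off + 2 * k + 1, i, j] = vals.std()
                feats[off + 2 * nr, i, j] = window.mean()
                feats[off + 2 * nr + 1, i, j] = window.std()
                feats[off + 2 * nr + 2, i, j] = np.percentile(window, 5)
                # darkness-weighted second moments (cells are darker than
                # the bright-field background)
                dark = np.clip(np.median(window) - window, 0, None)
                mass = dark.sum() + 1e-9
                mx = (dark * xx).sum() / mass
                my = (dark * yy).sum() / mass
                cxx = (dark * (xx - mx) ** 2).sum() / mass
                cyy = (dark * (yy - my) ** 2).sum() / mass
                cxy = (dark * (xx - mx) * (yy - my)).sum() / mass
                trace = cxx + cyy
                disc = max(trace * trace / 4 - (cxx * cyy - cxy**2), 0.0) ** 0.5
                lam_max = trace / 2 + disc
                lam_min = max(trace / 2 - disc, 1e-9)
                feats[moff, i, j] = mass / rwin**2
                feats[moff + 1, i, j] = np.sqrt(trace)
                feats[moff + 2, i, j] = np.sqrt(lam_max / lam_min)
                feats[moff + 3, i, j] = (dark > 0.15).mean()
                # oriented extents: direct linear cues for width/height
                # regression of thin, rotated shapes
                feats[moff + 4, i, j] = np.sqrt(cxx)
                feats[moff + 5, i, j] = np.sqrt(cyy)
                feats[moff + 6, i, j] = cxy / np.sqrt(cxx * cyy + 1e-9)
        return feats

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        """Apply the per-channel scaler fitted on the training set."""
        return (feats - self.feature_mean_[:, None, None]) / self.feature_std_[:, None, None]

    # -- model -------------------------------------------------------------
    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        c = self._n_feature_channels
        self.feature_channels_ = c
        self.cags_ = (
            CAGS(CagsConfig(channels=c), seed=int(rng.integers(2**31 - 1)))
            if self.use_cags
            else None
        )
        self.head_ = PointwiseConv(c, 5 + self.n_classes, rng)
        # start objectness pessimistic so early predictions are sparse
        self.head_.bias.data[0] = -2.0

    def _modules(self):
        mods = [self.head_]
        if self.cags_ is not None:
            mods.append(self.cags_)
        return mods

    def _parameters(self):
        return [p for m in self._modules() for p in m.parameters()]

    def _forward(self, feats: np.ndarray):
        """[C, G, G] features -> head output Tensor [5 + K, G*G]."""
        g = self._grid_size()
        x = feats
        if self.cags_ is not None:
            x = self.cags_(x)
        flat = x.reshape(self.feature_channels_, g * g)
        return self.head_(flat)

    def _anchor(self) -> float:
        return self.anchor_scale * self.stride

    def _targets(self, records):
        """Cell assignment for one image.

        The cell containing an object's center carries objectness 1.
        Every cell whose center lies inside the object's box carries the
        class target and the box regression target (the extended-range
        offset decode can reach the object center from any such cell);
        covered non-center cells are excluded from the objectness loss
        rather than forced to call themselves background.
        """
        g = self._grid_size()
        obj = np.zeros(g * g)
        obj_weight = np.ones(g * g)
        cls_t: dict[int, int] = {}
        box_t: dict[int, Box] = {}
        inside_t: dict[int, int] = {}
        for cid, box in records:
            col = min(int(box.cx * g), g - 1)
            row = min(int(box.cy * g), g - 1)
            cell = row * g + col
            if cell in cls_t:
                continue  # one object per cell at this scale
            obj[cell] = 1.0
            obj_weight[cell] = self.obj_pos_weight
            cls_t[cell] = int(cid)
            box_t[cell] = box
            # cells whose center falls inside the gt box and can reach its
            # center with the extended offset range
            x1, y1, x2, y2 = box.to_corners()
            for rr in range(g):
                cy_cell = (rr + 0.5) / g
                if not y1 <= cy_cell <= y2:
                    continue
                if not -0.45 < box.cy * g - rr < 1.45:
                    continue
                for cc in range(g):
                    cx_cell = (cc + 0.5) / g
                    if x1 <= cx_cell <= x2 and -0.45 < box.cx * g - cc < 1.45:
                        other = rr * g + cc
                        if other != cell:
                            inside_t.setdefault(other, (int(cid), box))
                            if obj[other] == 0:
                                obj_weight[other] = 0.0  # ignore in objectness
        for cell, (cid, box) in inside_t.items():
            cls_t.setdefault(cell, cid)
            box_t.setdefault(cell, box)
        box_cells = np.array(sorted(box_t), dtype=int)
        boxes = np.array(
            [[box_t[c].cx, box_t[c].cy, box_t[c].w, box_t[c].h] for c in box_cells]
        )
        cls_cells = np.array(sorted(cls_t), dtype=int)
        cls_ids = np.array([cls_t[c] for c in cls_cells], dtype=int)
        return obj, obj_weight, (cls_cells, cls_ids), (box_cells, boxes)

    def _loss(self, feats: np.ndarray, records):
        g = self._grid_size()
        y = self._forward(feats)
        obj_target, obj_weight, (cls_cells, cls_ids), (box_cells, gt_boxes) = self._targets(records)
        obj_logits = y[0]
        loss_obj = _weighted_bce_with_logits(obj_logits, obj_target, obj_weight)
        parts = {"obj": float(ad.asdata(loss_obj))}
        total = loss_obj
        if box_cells.size:
            k = self.n_classes
            # class cross-entropy on all object-covered cells
            z = y[(np.arange(5, 5 + k)[:, None], cls_cells[None, :])]
            zmax = ad.asdata(z).max(axis=0)
            lse = ad.log(ad.tsum(ad.exp(z - zmax), axis=0)) + zmax
            picked = y[(5 + cls_ids, cls_cells)]
            loss_cls = ad.tmean(lse - picked)
            # box regression on center cells only
            t = y[(np.arange(1, 5)[:, None], box_cells[None, :])]
            rows, cols = box_cells // g, box_cells % g
            scale = self.stride / self.image_size
            cx = (cols + 2.0 * ad.sigmoid(t[0]) - 0.5) * scale
            cy = (rows + 2.0 * ad.sigmoid(t[1]) - 0.5) * scale
            anchor_n = self._anchor() / self.image_size
            bw = anchor_n * ad.exp(ad.clip(t[2], -4.0, 4.0))
            bh = anchor_n * ad.exp(ad.clip(t[3], -4.0, 4.0))
            pred_boxes = ad.stack([cx, cy, bw, bh], axis=0).transpose(1, 0)
            loss_box = batched_loss(pred_boxes, gt_boxes, kind=self.loss_kind,
                                    reduction="mean", theta=self.theta)
            total = total + loss_cls + self.box_weight * loss_box
            parts["cls"] = float(ad.asdata(loss_cls))
            parts["box"] = float(ad.asdata(loss_box))
        else:
            parts["cls"] = 0.0
            parts["box"] = 0.0
        parts["total"] = float(ad.asdata(total))
        return total, parts

    def _ridge_init(self, feats, annotations, lam: float = 1e-2) -> None:
        """Closed-form initialization of the head by ridge regression.

        The SGD step budget of a short run is far too small to fit a
        7-way softmax from random weights, so the head is first solved in
        closed form on the (attention-gated) training features: objectness
        rows regress to +/-2 logit targets, class rows to one-vs-rest
        +/-2 targets on object-covered cells, and box rows to the encoded
        ground-truth offsets on center cells.  The subsequent epochs refine
        this initialization — attention block included — with the actual
        detection losses.
        """
        g = self._grid_size()
        c = self.feature_channels_
        gated, obj_rows, cls_cols, cls_ids, box_cols, box_t = [], [], [], [], [], []
        offset = 0
        for f, recs in zip(feats, annotations):
            z = ad.asdata(self.cags_(f)) if self.cags_ is not None else f
            gated.append(z.reshape(c, g * g))
            obj, _, (cc, ci), (bc, bx) = self._targets(recs)
            obj_rows.append(obj)
            cls_cols.extend(offset + cc)
            cls_ids.extend(ci)
            for cell, brow in zip(bc, bx):
                box_cols.append(offset + cell)
                box_t.append(
                    encode_offsets(Box(*brow), cell // g, cell % g, self.stride,
                                   self._anchor(), self.image_size)
                )
            offset += g * g
        xa = np.vstack([np.concatenate(gated, axis=1), np.ones((1, offset))])

        def solve(cols, targets):
            xs = xa[:, cols] if cols is not None else xa
            a = xs @ xs.T + lam * xs.shape[1] * np.eye(xs.shape[0])
            return np.linalg.solve(a, xs @ targets.T).T

        w_obj = solve(None, (np.concatenate(obj_rows) * 4.0 - 2.0)[None, :])
        w = np.zeros((5 + self.n_classes, c + 1))
        w[0] = w_obj
        if box_cols:
            w[1:5] = solve(np.array(box_cols), np.array(box_t).T)
            onehot = -np.ones((self.n_classes, len(cls_cols)))
            onehot[np.array(cls_ids), np.arange(len(cls_cols))] = 1.0
            w[5:] = solve(np.array(cls_cols), onehot * 2.0)
        self.head_.weight.data = w[:, :c]
        self.head_.bias.data = w[:, c:]

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "TinyDetector":
        """Train on images `X` and annotations `y`.

        Parameters
        ----------
        X : sequence of 2-D arrays, each image_size x image_size in [0, 1]
        y : sequence of lists of (class_id, Box) with normalized boxes
        """
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        self._grid_size()
        self._build()
        raw = [self._features(np.asarray(img, dtype=np.float64)) for img in X]
        stacked = np.stack(raw)
        self.feature_mean_ = stacked.mean(axis=(0, 2, 3))
        self.feature_std_ = stacked.std(axis=(0, 2, 3)) + 1e-6
        feats = [self._standardize(f) for f in raw]
        self._ridge_init(feats, y)
        if self.optimizer == "adam":
            opt = Adam(self._parameters(), lr=self.learning_rate,
                       weight_decay=self.weight_decay)
        elif self.optimizer == "sgd":
            opt = SGD(self._parameters(), lr=self.learning_rate, momentum=self.momentum,
                      weight_decay=self.weight_decay)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        rng = np.random.default_rng(self.seed + 1)
        self.history_ = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            sums = {"total": 0.0, "obj": 0.0, "cls": 0.0, "box": 0.0}
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                opt.zero_grad()
                batch_loss = None
                for i in batch:
                    loss, parts = self._loss(feats[i], y[i])
                    for key in sums:
                        sums[key] += parts[key]
                    batch_loss = loss if batch_loss is None else batch_loss + loss
                batch_loss = batch_loss * (1.0 / len(batch))
                if not np.isfinite(ad.asdata(batch_loss)):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: non-finite loss "
                        f"(components {parts})"
                    )
                batch_loss.backward()
                opt.step()
            self.history_.append(
                {"epoch": epoch, **{k: v / n for k, v in sums.items()},
                 "loss": sums["total"] / n}
            )
        return self

    def predict(self, X) -> list[list[DetectionRecord]]:
        """Detections per image, after score filtering and per-class NMS."""
        if not hasattr(self, "head_"):
            raise RuntimeError("detector is not fitted")
        g = self._grid_size()
        out: list[list[DetectionRecord]] = []
        for idx, img in enumerate(X):
            feats = self._standardize(self._features(np.asarray(img, dtype=np.float64)))
            y = ad.asdata(self._forward(feats))
            obj = 1.0 / (1.0 + np.exp(-y[0]))
            zc = y[5:]
            zc = zc - zc.max(axis=0)
            probs = np.exp(zc) / np.exp(zc).sum(axis=0)
            records = []
            for cell in range(g * g):
                score = float(obj[cell] * probs[:, cell].max())
                if score < self.conf_threshold:
                    continue
                cls = int(probs[:, cell].argmax())
                box = decode_offsets(
                    y[1:5, cell], cell // g, cell % g, self.stride, self._anchor(),
                    self.image_size,
                )
                records.append(DetectionRecord(str(idx), cls, min(score, 1.0), box))
            out.append(_nms(records, self.nms_iou))
        return out

    def evaluate(self, X, y) -> EvalResult:
        """Predict on `X` and evaluate against annotations `y`."""
        preds = [r for recs in self.predict(X) for r in recs]
        gts = [
            DetectionRecord(str(i), cid, 1.0, box)
            for i, recs in enumerate(y)
            for cid, box in recs
        ]
        return mean_ap(preds, gts)

    def score(self, X, y) -> float:
        """mAP@0.5 on (X, y), the scalar sklearn scoring hook."""
        return self.evaluate(X, y).map50

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = [p.data for p in self._parameters()]
        np.savez(path, *arrays, params=json.dumps(self.get_params()),
                 feature_mean=self.feature_mean_, feature_std=self.feature_std_)

    def load_weights(self, path) -> "TinyDetector":
        data = np.load(path, allow_pickle=False)
        self.set_params(**json.loads(str(data["params"])))
        self._build()
        self.feature_mean_ = data["feature_mean"]
        self.feature_std_ = data["feature_std"]
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 3)]
        own = self._parameters()
        if len(arrays) != len(own):
            raise ValueError("checkpoint does not match the configured architecture")
        for p, a in zip(own, arrays):
            p.data = a.astype(np.float64)
        return self


def _load_split(dataset_dir: Path, split: str):
    images, annots = [], []
    img_dir = dataset_dir / "images" / split
    for img_path in sorted(img_dir.glob("*.png")):
        lbl_path = dataset_dir / "labels" / split / (img_path.stem + ".txt")
        images.append(load_image(img_path))
        annots.append(read_yolo_labels(lbl_path))
    return images, annots


def smoke_train(dataset_dir, config: TrainConfig | None = None, out_dir=None):
    """End-to-end desk-scale run: load a synthetic dataset, train, evaluate.

    Returns ``(detector, eval_result)``; when `out_dir` is given, writes a
    plain-text training log, a checkpoint, the test-split evaluation report
    and a run manifest recording every configuration default.
    """
    config = config or TrainConfig.smoke()
    dataset_dir = Path(dataset_dir)
    train_x, train_y = _load_split(dataset_dir, "train")
    test_x, test_y = _load_split(dataset_dir, "test")
    if not train_x:
        raise ValueError(f"no training images under {dataset_dir}")
    n_classes = len(json.loads((dataset_dir / "manifest.json").read_text())["class_names"])
    det = TinyDetector(
        image_size=config.image_size,
        n_classes=n_classes,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        epochs=config.epochs,
        loss_kind=config.loss_kind,
        use_cags=config.use_cags,
        seed=config.seed,
    )
    det.fit(train_x, train_y)
    result = det.evaluate(test_x, test_y)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        log_lines = [
            f"epoch {h['epoch']} loss {h['loss']:.6f} obj {h['obj']:.6f} "
            f"cls {h['cls']:.6f} box {h['box']:.6f}"
            for h in det.history_
        ]
        (out / "train_log.txt").write_text("\n".join(log_lines) + "\n")
        det.save(out / "checkpoint.npz")
        result.to_json(out / "eval.json")
        manifest = {
            "config": asdict(config),
            "detector_params": det.get_params(),
            "matching_protocol": "greedy by descending confidence, one-to-one ground truths",
            "ap_interpolation": "all-points monotone envelope",
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return det, result
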