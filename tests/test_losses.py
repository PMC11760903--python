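import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from algadet import autodiff as ad
from algadet.boxes import Box, InvalidBoxError, enclosure_geometry
from algadet.losses import (
    InvalidGeometryError,
    batched_breakdown,
    batched_loss,
    ciou_loss,
    iou,
    siou_angle_cost,
    siou_distance_cost,
    siou_loss,
    siou_shape_cost,
)

from oracles import ciou_scalar, iou_scalar, random_box_pairs, siou_scalar

coord = st.floats(-20, 20, allow_nan=False)
extent = st.floats(0.05, 10, allow_nan=False)
box_st = st.builds(Box, cx=coord, cy=coord, w=extent, h=extent)


class TestIoU:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Box(5, 5, 2, 2), Box(5, 5, 2, 2), 1.0),
            (Box(0, 0, 2, 2), Box(10, 10, 2, 2), 0.0),
            (Box(1, 1, 2, 2), Box(2, 2, 2, 2), 1 / 7),
        ],
    )
    def test_examples(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)

    @given(box_st, box_st)
    def test_bounds_and_symmetry(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a), abs=1e-12)

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            iou(np.array([0, 0, -1, 2]), np.array([0, 0, 1, 1]))


class TestCIoU:
    def test_identity(self):
        bd = ciou_loss(Box(5, 5, 2, 2), Box(5, 5, 2, 2))
        assert bd.loss == pytest.approx(0.0, abs=1e-12)
        assert bd.ciou_penalty_v == 0.0
        assert bd.ciou_alpha == 0.0
        assert bd.iou == 1.0

    def test_same_aspect_ratio_reduces_to_center_penalty(self):
        # equal aspect ratios zero out the v term, leaving 1 - IoU + rho^2/c^2
        bd = ciou_loss(Box(0, 0, 2, 2), Box(4, 0, 2, 2))
        assert bd.ciou_penalty_v == pytest.approx(0.0, abs=1e-15)
        assert bd.loss == pytest.approx(1.0 + 16.0 / 40.0, abs=1e-12)

    def test_aspect_penalty_value(self):
        bd = ciou_loss(Box(0, 0, 2, 4), Box(0, 0, 4, 2))
        expected_v = (4 / math.pi**2) * (math.atan(2) - math.atan(0.5)) ** 2
        assert bd.ciou_penalty_v == pytest.approx(expected_v, abs=1e-12)
        assert bd.loss == pytest.approx(ciou_scalar((0, 0, 2, 4), (0, 0, 4, 2)), abs=1e-12)


class TestSIoUComponents:
    @pytest.mark.parametrize(
        "dx,dy,expected",
        [(3, 0, 0.0), (0, 3, 0.0), (3, 3, 1.0)],
    )
    def test_angle_cost_alignments(self, dx, dy, expected):
        geom = enclosure_geometry(Box(0, 0, 2, 2), Box(dx, dy, 2, 2))
        assert siou_angle_cost(geom) == pytest.approx(expected, abs=1e-12)

    def test_angle_cost_coincident_centers(self):
        geom = enclosure_geometry(Box(0, 0, 2, 2), Box(0, 0, 4, 4))
        assert siou_angle_cost(geom) == 0.0

    def test_angle_cost_inconsistent_geometry(self):
        from algadet.boxes import EnclosureGeometry

        bad = EnclosureGeometry(4, 4, 5.66, 0.0, 2.0, 1.0)
        with pytest.raises(InvalidGeometryError):
            siou_angle_cost(bad)

    def test_distance_cost_examples(self):
        # dx/enclose_w = 1/2, dy = 0, angle cost 0 -> gamma 2
        from algadet.boxes import EnclosureGeometry

        geom = EnclosureGeometry(4, 4, math.sqrt(32), 2.0, 0.0, 2.0)
        assert siou_distance_cost(geom, 0.0) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        # angle cost 1 halves the rate
        assert siou_distance_cost(geom, 1.0) == pytest.approx(1 - math.exp(-0.25), abs=1e-12)

    def test_distance_cost_zero_at_coincident_centers(self):
        geom = enclosure_geometry(Box(1, 1, 2, 2), Box(1, 1, 3, 1))
        assert siou_distance_cost(geom, siou_angle_cost(geom)) == 0.0

    def test_shape_cost(self):
        assert siou_shape_cost(Box(0, 0, 2, 2), Box(0, 0, 2, 2)) == 0.0
        got = siou_shape_cost(Box(0, 0, 2, 3), Box(0, 0, 4, 3), theta=4)
        assert got == pytest.approx((1 - math.exp(-0.5)) ** 4, abs=1e-12)

    @given(box_st, box_st)
    def test_shape_cost_symmetric(self, a, b):
        assert siou_shape_cost(a, b) == pytest.approx(siou_shape_cost(b, a), abs=1e-12)

    def test_shape_cost_invalid_theta(self):
        with pytest.raises(ValueError):
            siou_shape_cost(Box(0, 0, 1, 1), Box(0, 0, 2, 2), theta=0)


class TestSIoULoss:
    def test_identity(self):
        assert siou_loss(Box(3, 3, 1, 2), Box(3, 3, 1, 2)).loss == pytest.approx(0, abs=1e-12)

    def test_horizontal_worked_example(self):
        bd = siou_loss(Box(0, 0, 2, 2), Box(4, 0, 2, 2))
        assert bd.iou == 0.0
        assert bd.angle_cost == pytest.approx(0.0, abs=1e-12)
        assert bd.shape_cost == 0.0
        assert bd.distance_cost == pytest.approx(1 - math.exp(-8 / 9), abs=1e-12)
        assert bd.loss == pytest.approx(1 + (1 - math.exp(-8 / 9)) / 2, abs=1e-12)

    @given(box_st, box_st)
    def test_decomposition_holds(self, a, b):
        bd = siou_loss(a, b)
        assert bd.loss == pytest.approx(
            1 - bd.iou + (bd.distance_cost + bd.shape_cost) / 2, abs=1e-9
        )

    @given(box_st, box_st)
    def test_component_bounds(self, a, b):
        bd = siou_loss(a, b)
        assert 0.0 <= bd.angle_cost <= 1.0
        assert 0.0 <= bd.distance_cost < 2.0
        assert 0.0 <= bd.shape_cost < 2.0
        assert 0.0 <= bd.loss < 3.0

    def test_monotone_approach_along_axis(self):
        # same shapes, centers on a horizontal line: loss shrinks as gap closes
        losses = [siou_loss(Box(x, 0, 2, 2), Box(0, 0, 2, 2)).loss for x in
                  np.linspace(5, 0, 40)]
        assert all(l1 <= l0 + 1e-12 for l0, l1 in zip(losses, losses[1:]))

    def test_equal_aspect_motivation(self):
        # same aspect ratio, different size: CIoU's v vanishes exactly while
        # SIoU's shape cost stays positive — the reason to prefer SIoU
        pred, gt = Box(0, 0, 2, 2), Box(0, 0, 4, 4)
        assert ciou_loss(pred, gt).ciou_penalty_v == 0.0
        assert siou_loss(pred, gt).shape_cost > 0.0

    @given(box_st, box_st, st.floats(-30, 30), st.floats(-30, 30),
           st.floats(0.1, 10))
    def test_translation_and_scale_invariance(self, a, b, tx, ty, k):
        base = siou_loss(a, b)
        shifted = siou_loss(
            Box(a.cx + tx, a.cy + ty, a.w, a.h), Box(b.cx + tx, b.cy + ty, b.w, b.h)
        )
        assert shifted.loss == pytest.approx(base.loss, abs=1e-7)
        scaled = siou_loss(
            Box(a.cx * k, a.cy * k, a.w * k, a.h * k),
            Box(b.cx * k, b.cy * k, b.w * k, b.h * k),
        )
        for field in ("iou", "angle_cost", "distance_cost", "shape_cost"):
            assert getattr(scaled, field) == pytest.approx(getattr(base, field), abs=1e-7)


class TestOracleEquivalence:
    def test_scalar_transcription_agreement(self, rng):
        pairs = random_box_pairs(rng, 1000)
        preds = np.array([p for p, _ in pairs])
        gts = np.array([g for _, g in pairs])
        for kind, oracle in (("iou", lambda p, g: 1 - iou_scalar(p, g)),
                             ("ciou", ciou_scalar), ("siou", siou_scalar)):
            batched = batched_loss(preds, gts, kind=kind, reduction="none")
            expected = np.array([oracle(tuple(p), tuple(g)) for p, g in pairs])
            assert np.abs(batched - expected).max() < 1e-6

    def test_batched_matches_scalar_loop(self, rng):
        pairs = random_box_pairs(rng, 200)
        preds = np.array([p for p, _ in pairs])
        gts = np.array([g for _, g in pairs])
        batched = batched_loss(preds, gts, kind="siou", reduction="none")
        loop = np.array([siou_loss(Box(*p), Box(*g)).loss for p, g in pairs])
        assert np.abs(batched - loop).max() < 1e-6


class TestBatchedLoss:
    def test_empty(self):
        assert batched_loss([], [], reduction="none").size == 0
        assert batched_loss([], [], reduction="mean") == 0.0

    def test_identical_mean_zero(self, rng):
        b = np.column_stack([rng.uniform(-5, 5, 20), rng.uniform(-5, 5, 20),
                             rng.uniform(0.1, 4, 20), rng.uniform(0.1, 4, 20)])
        for kind in ("iou", "ciou", "siou"):
            assert batched_loss(b, b, kind=kind, reduction="mean") == pytest.approx(0, abs=1e-12)

    def test_reductions_consistent(self, rng):
        pairs = random_box_pairs(rng, 37)
        preds = np.array([p for p, _ in pairs])
        gts = np.array([g for _, g in pairs])
        per = batched_loss(preds, gts, reduction="none")
        assert batched_loss(preds, gts, reduction="sum") == pytest.approx(per.sum())
        assert batched_loss(preds, gts, reduction="mean") == pytest.approx(per.mean())

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            batched_loss(np.zeros((2, 4)) + 1, np.ones((3, 4)))

    def test_unknown_kind_and_reduction(self):
        b = np.ones((1, 4))
        with pytest.raises(ValueError):
            batched_loss(b, b, kind="giou")
        with pytest.raises(ValueError):
            batched_loss(b, b, reduction="median")

    @pytest.mark.parametrize("kind", ["iou", "ciou", "siou"])
    def test_gradients_finite(self, rng, kind):
        pairs = random_box_pairs(rng, 64)
        preds = ad.Tensor(np.array([p for p, _ in pairs]), requires_grad=True)
        gts = np.array([g for _, g in pairs])
        loss = batched_loss(preds, gts, kind=kind, reduction="mean")
        loss.backward()
        assert np.all(np.isfinite(preds.grad))

    def test_gradient_matches_finite_differences(self, rng):
        pred = np.array([[0.6, 0.4, 1.4, 0.9]])
        gt = np.array([[0.3, 0.7, 1.0, 1.3]])
        t = ad.Tensor(pred, requires_grad=True)
        batched_loss(t, gt, kind="siou", reduction="sum").backward()
        eps = 1e-6
        for j in range(4):
            bumped = pred.copy()
            bumped[0, j] += eps
            up = float(batched_loss(bumped, gt, kind="siou", reduction="sum"))
            bumped[0, j] -= 2 * eps
            down = float(batched_loss(bumped, gt, kind="siou", reduction="sum"))
            assert t.grad[0, j] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestBatchedBreakdown:
    def test_bounds_on_random_pairs(self, rng):
        pairs = random_box_pairs(rng, 300)
        preds = np.array([p for p, _ in pairs])
        gts = np.array([g for _, g in pairs])
        bd = batched_breakdown(preds, gts, kind="siou")
        assert np.all((bd.iou >= 0) & (bd.iou <= 1))
        assert np.all((bd.angle_cost >= 0) & (bd.angle_cost <= 1))
        assert np.all((bd.distance_cost >= 0) & (bd.distance_cost < 2))
        assert np.all((bd.shape_cost >= 0) & (bd.shape_cost < 2))
        assert np.all(np.isfinite(bd.loss))
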