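"""IoU-family loss functions against independent step-by-step oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box as shapely_box

from seedgrid.detector.losses import (
    BBox,
    LossState,
    ciou_loss,
    iou,
    wiou_v1,
    wiou_v3,
    wiou_v3_factor,
)
from seedgrid.errors import ConfigError, DataError


def _random_box(rng) -> BBox:
    return BBox(
        cx=rng.uniform(0.2, 0.8),
        cy=rng.uniform(0.2, 0.8),
        w=rng.uniform(0.05, 0.5),
        h=rng.uniform(0.05, 0.5),
    )


def _oracle_iou(a: BBox, b: BBox) -> float:
    """Independent IoU via shapely polygon intersection."""
    pa = shapely_box(a.x_lo, a.y_lo, a.x_hi, a.y_hi)
    pb = shapely_box(b.x_lo, b.y_lo, b.x_hi, b.y_hi)
    inter = pa.intersection(pb).area
    return inter / (pa.area + pb.area - inter)


def _oracle_ciou(pred: BBox, gt: BBox) -> float:
    """Step-by-step evaluation: overlap, center distance, aspect terms."""
    l_iou = 1.0 - _oracle_iou(pred, gt)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    wg = max(pred.x_hi, gt.x_hi) - min(pred.x_lo, gt.x_lo)
    hg = max(pred.y_hi, gt.y_hi) - min(pred.y_lo, gt.y_lo)
    v = 4 / math.pi**2 * (math.atan(pred.w / pred.h) - math.atan(gt.w / gt.h)) ** 2
    alpha = 0.0 if v == 0 else v / (l_iou + v)
    return l_iou + rho2 / (wg**2 + hg**2) + alpha * v


def _oracle_wiou_v1(pred: BBox, gt: BBox) -> float:
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    wg = max(pred.x_hi, gt.x_hi) - min(pred.x_lo, gt.x_lo)
    hg = max(pred.y_hi, gt.y_hi) - min(pred.y_lo, gt.y_lo)
    return math.exp(rho2 / (wg**2 + hg**2)) * (1.0 - _oracle_iou(pred, gt))


class TestIou:
    def test_identical_unit_squares(self):
        b = BBox(0.5, 0.5, 1, 1)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BBox(0, 0, 1, 1), BBox(5, 5, 1, 1)) == 0.0

    def test_half_offset_unit_squares(self):
        a = BBox(0.5, 0.5, 1, 1)
        b = BBox(1.0, 0.5, 1, 1)
        assert iou(a, b) == pytest.approx(1 / 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_box(rng), _random_box(rng)
        assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)
        dx, dy = rng.uniform(-3, 3, size=2)
        a2 = BBox(a.cx + dx, a.cy + dy, a.w, a.h)
        b2 = BBox(b.cx + dx, b.cy + dy, b.w, b.h)
        assert iou(a2, b2) == pytest.approx(iou(a, b), abs=1e-9)


class TestCiou:
    def test_perfect_match_is_zero(self):
        b = BBox(0.3, 0.7, 0.2, 0.1)
        assert ciou_loss(b, b) == 0.0

    def test_concentric_double_scale(self):
        """Same aspect, same center, 2x size: only the overlap term remains."""
        gt = BBox(0.5, 0.5, 0.2, 0.1)
        pred = BBox(0.5, 0.5, 0.4, 0.2)
        assert ciou_loss(pred, gt) == pytest.approx(0.75)

    def test_lower_bound_is_iou_loss(self, rng):
        for _ in range(200):
            a, b = _random_box(rng), _random_box(rng)
            assert ciou_loss(a, b) >= 1.0 - iou(a, b) >= 0.0

    def test_zero_sized_box_rejected(self):
        with pytest.raises(DataError):
            ciou_loss(BBox(0.5, 0.5, 0, 0.1), BBox(0.5, 0.5, 0.1, 0.1))


class TestWiou:
    def test_v1_zero_at_perfect_match(self):
        b = BBox(0.5, 0.5, 0.2, 0.2)
        assert wiou_v1(b, b) == 0.0

    def test_v1_concentric_equals_iou_loss(self):
        gt = BBox(0.5, 0.5, 0.2, 0.1)
        pred = BBox(0.5, 0.5, 0.4, 0.2)
        assert wiou_v1(pred, gt) == pytest.approx(1.0 - iou(pred, gt))

    def test_v1_offset_fixture(self):
        pred = BBox(0.4, 0.5, 0.2, 0.2)
        gt = BBox(0.6, 0.5, 0.2, 0.2)
        assert wiou_v1(pred, gt) == pytest.approx(_oracle_wiou_v1(pred, gt), abs=1e-12)

    @pytest.mark.parametrize(
        "beta,expected",
        [(3.0, 1.0), (0.0, 0.0), (6.0, 6.0 / (3 * 1.9**3))],
    )
    def test_v3_factor_values(self, beta, expected):
        assert wiou_v3_factor(beta) == pytest.approx(expected, abs=1e-12)

    def test_v3_factor_unimodal(self):
        grid = np.arange(0.1, 10.01, 0.1)
        r = np.array([wiou_v3_factor(b) for b in grid])
        peak = int(np.argmax(r))
        assert 0 < peak < len(grid) - 1
        assert (np.diff(r[: peak + 1]) > 0).all()
        assert (np.diff(r[peak:]) < 0).all()

    def test_v3_factor_rejects_negative(self):
        with pytest.raises(ConfigError):
            wiou_v3_factor(-0.1)

    def test_v3_perfect_match_is_zero(self):
        b = BBox(0.5, 0.5, 0.2, 0.2)
        loss, _ = wiou_v3(b, b, LossState())
        assert loss == 0.0

    def test_v3_beta_one_scaling(self):
        """When current loss equals the running mean, r(1) = 1.9^2 / 3."""
        pred = BBox(0.4, 0.5, 0.2, 0.2)
        gt = BBox(0.6, 0.5, 0.2, 0.2)
        l_iou = 1.0 - iou(pred, gt)
        state = LossState(running_mean_iou_loss=l_iou)
        loss, new_state = wiou_v3(pred, gt, state)
        assert loss == pytest.approx((1.9**2 / 3) * wiou_v1(pred, gt), abs=1e-12)
        # EMA of a constant is the constant
        assert new_state.running_mean_iou_loss == pytest.approx(l_iou)

    def test_v3_batch_matches_two_pass_oracle(self, rng):
        """EMA bookkeeping equals an explicit sequential recomputation."""
        pairs = [(_random_box(rng), _random_box(rng)) for _ in range(30)]
        state = LossState()
        ours = []
        for p, g in pairs:
            loss, state = wiou_v3(p, g, state)
            ours.append(loss)
        mean = 1.0
        for (p, g), got in zip(pairs, ours):
            l_iou = 1.0 - _oracle_iou(p, g)
            beta = l_iou / mean
            expected = (
                beta / (3.0 * 1.9 ** (beta - 3.0))
            ) * _oracle_wiou_v1(p, g)
            assert got == pytest.approx(expected, abs=1e-9)
            mean = 0.9 * mean + 0.1 * l_iou

    def test_v3_uninitialized_state_instructs_warmup(self):
        state = LossState(running_mean_iou_loss=0.0)
        with pytest.raises(ConfigError, match="warm"):
            wiou_v3(BBox(0.5, 0.5, 0.1, 0.1), BBox(0.6, 0.5, 0.1, 0.1), state)


def test_all_losses_match_oracle_on_random_pairs(rng):
    """100 random pairs, every loss to 1e-9 against the independent oracle."""
    for _ in range(100):
        pred, gt = _random_box(rng), _random_box(rng)
        assert iou(pred, gt) == pytest.approx(_oracle_iou(pred, gt), abs=1e-9)
        assert ciou_loss(pred, gt) == pytest.approx(_oracle_ciou(pred, gt), abs=1e-9)
        assert wiou_v1(pred, gt) == pytest.approx(_oracle_wiou_v1(pred, gt), abs=1e-9)
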