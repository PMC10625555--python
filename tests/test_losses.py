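"""Loss functions: hand-computed values, decompositions, gradient checks."""

import numpy as np
import pytest

from otoseg.losses import (
    LossConfig,
    composite_loss,
    cross_entropy_loss,
    heatmap_mse,
    log_cosh_dice_loss,
    seg_loss_variant,
    soft_dice_loss,
    squared_dice_loss,
)
from otoseg.model import PredictionBundle
from otoseg.nn import Tensor


def _mask(shape, idx):
    m = np.zeros(shape, dtype=np.float64)
    for i in idx:
        m[i] = 1.0
    return m


class TestSoftDice:
    def test_perfect_prediction_near_zero(self, rng):
        t = (rng.random((8, 8, 8)) < 0.3).astype(np.float64)
        assert t.sum() >= 100
        assert soft_dice_loss(t, t, eps=1e-5).item() < 1e-4

    def test_disjoint_masks_near_one(self):
        a = _mask((4, 4, 4), [(0, 0, 0), (1, 1, 1)])
        b = _mask((4, 4, 4), [(2, 2, 2), (3, 3, 3)])
        assert soft_dice_loss(a, b).item() > 1 - 1e-4

    def test_half_overlap_hand_count(self):
        # |a| = |b| = 4, overlap 2 -> dice 4/8 -> loss 0.5
        a = _mask((4, 4, 4), [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        b = _mask((4, 4, 4), [(0, 0, 2), (0, 0, 3), (1, 0, 0), (1, 0, 1)])
        assert soft_dice_loss(a, b, eps=0.0).item() == pytest.approx(0.5)
        assert squared_dice_loss(a, b, eps=0.0).item() == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestCrossEntropy:
    def test_perfect_prediction(self):
        t = _mask((4, 4, 4), [(1, 1, 1)])
        assert cross_entropy_loss(t, t).item() <= 1e-5

    def test_uniform_half_gives_ln2(self):
        t = _mask((4, 4, 4), [(0, 0, 0)])
        p = np.full((4, 4, 4), 0.5)
        assert cross_entropy_loss(p, t).item() == pytest.approx(np.log(2), rel=1e-6)

    def test_monotone_toward_target(self):
        t = np.ones((3, 3, 3))
        losses = [cross_entropy_loss(np.full((3, 3, 3), p), t).item()
                  for p in (0.5, 0.7, 0.9, 0.99)]
        assert losses == sorted(losses, reverse=True)


class TestHeatmapMSE:
    def test_zero_at_equality(self, rng):
        h = rng.normal(size=(3, 4, 4, 4))
        assert heatmap_mse(h, h).item() == 0.0

    def test_constant_offset_squares(self, rng):
        h = rng.normal(size=(3, 4, 4, 4))
        assert heatmap_mse(h + 0.3, h).item() == pytest.approx(0.09, rel=1e-5)

    def test_quadratic_homogeneity(self, rng):
        h = rng.normal(size=(3, 4, 4, 4))
        d = rng.normal(size=(3, 4, 4, 4))
        l1 = heatmap_mse(h + d, h).item()
        l2 = heatmap_mse(h + 2 * d, h).item()
        assert l2 == pytest.approx(4 * l1, rel=1e-6)


class TestVariants:
    def test_all_variants_vanish_at_perfect_prediction(self, rng):
        t = (rng.random((6, 6, 6)) < 0.4).astype(np.float64)
        for name in ("ce_plus_dice", "dice", "squared_dice", "log_cosh_dice", "ce"):
            assert seg_loss_variant(name)(t, t).item() < 1e-3

    def test_log_cosh_below_dice(self, rng):
        for _ in range(100):
            p = rng.random((5, 5, 5))
            t = (rng.random((5, 5, 5)) < 0.3).astype(np.float64)
            d = soft_dice_loss(p, t).item()
            lc = log_cosh_dice_loss(p, t).item()
            assert lc <= d + 1e-12

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            seg_loss_variant("focal")
        with pytest.raises(ValueError):
            LossConfig(seg_loss="focal")


class TestComposite:
    def _bundle(self, rng, aux=False):
        seg = Tensor(rng.random((1, 4, 4, 4)))
        hm = Tensor(rng.normal(size=(3, 4, 4, 4)))
        aux_list = None
        if aux:
            aux_list = [(Tensor(rng.random((1, 2, 2, 2))),
                         Tensor(rng.normal(size=(3, 2, 2, 2))))]
        return PredictionBundle(seg=seg, heatmaps=hm, aux=aux_list)

    def test_single_terminal_reduction(self, rng):
        b = self._bundle(rng)
        ts = (rng.random((1, 4, 4, 4)) < 0.5).astype(np.float64)
        th = rng.normal(size=(3, 4, 4, 4))
        total, comps = composite_loss(b, ts, th, LossConfig())
        expect = (seg_loss_variant("ce_plus_dice")(b.seg, Tensor(ts)).item()
                  + heatmap_mse(b.heatmaps, Tensor(th)).item())
        assert total.item() == pytest.approx(expect, rel=1e-9)
        assert comps["total"] == pytest.approx(comps["seg"] + comps["heatmap"])

    def test_ce_plus_dice_decomposition(self, rng):
        p = rng.random((4, 4, 4))
        t = (rng.random((4, 4, 4)) < 0.5).astype(np.float64)
        combined = seg_loss_variant("ce_plus_dice")(p, t).item()
        separate = cross_entropy_loss(p, t).item() + soft_dice_loss(p, t).item()
        assert combined == pytest.approx(separate, abs=1e-12)

    def test_missing_aux_targets_rejected(self, rng):
        b = self._bundle(rng, aux=True)
        ts = np.zeros((1, 4, 4, 4))
        th = np.zeros((3, 4, 4, 4))
        with pytest.raises(ValueError, match="auxiliary"):
            composite_loss(b, ts, th, LossConfig())

    def test_permutation_invariance(self, rng):
        p = rng.random((4, 4, 4))
        t = (rng.random((4, 4, 4)) < 0.5).astype(np.float64)
        perm = rng.permutation(64)
        p2 = p.ravel()[perm].reshape(4, 4, 4)
        t2 = t.ravel()[perm].reshape(4, 4, 4)
        a = seg_loss_variant("ce_plus_dice")(p, t).item()
        b = seg_loss_variant("ce_plus_dice")(p2, t2).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_perfect_bundle_near_zero(self, rng):
        t = (rng.random((4, 4, 4)) < 0.4).astype(np.float64)
        th = rng.normal(size=(3, 4, 4, 4))
        b = PredictionBundle(seg=Tensor(np.clip(t[None], 1e-6, 1 - 1e-6)),
                             heatmaps=Tensor(th))
        total, _ = composite_loss(b, t[None], th, LossConfig())
        assert total.item() <= 1e-4


class TestGradientChecks:
    @pytest.mark.parametrize("name", ["ce_plus_dice", "dice", "squared_dice",
                                      "log_cosh_dice", "ce"])
    def test_seg_loss_finite_difference(self, name, rng):
        fn = seg_loss_variant(name)
        p0 = rng.uniform(0.05, 0.95, size=(4, 4, 4))
        t = (rng.random((4, 4, 4)) < 0.5).astype(np.float64)

        def f():
            pt = Tensor(p0.copy())
            pt.requires_grad = True
            return pt, fn(pt, t)

        pt, loss = f()
        loss.backward()
        g = pt.grad
        h = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            orig = p0[idx]
            p0[idx] = orig + h
            lp = fn(Tensor(p0), t).item()
            p0[idx] = orig - h
            lm = fn(Tensor(p0), t).item()
            p0[idx] = orig
            num = (lp - lm) / (2 * h)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-8)

    def test_heatmap_mse_finite_difference(self, rng):
        p0 = rng.normal(size=(3, 4, 4, 4))
        t = rng.normal(size=(3, 4, 4, 4))
        pt = Tensor(p0.copy())
        pt.requires_grad = True
        heatmap_mse(pt, t).backward()
        g = pt.grad
        h = 1e-6
        idx = (1, 2, 2, 2)
        orig = p0[idx]
        p0[idx] = orig + h
        lp = heatmap_mse(Tensor(p0), t).item()
        p0[idx] = orig - h
        lm = heatmap_mse(Tensor(p0), t).item()
        num = (lp - lm) / (2 * h)
        assert num == pytest.approx(g[idx], rel=1e-4)
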