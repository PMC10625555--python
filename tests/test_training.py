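"""Training loop: LR schedule, fold plans, gradient accumulation
equivalence, sampler behavior, descent smoke test, checkpoints."""

import numpy as np
import pytest

from otoseg.heatmap import HeatmapSchedule, render
from otoseg.io_core import ValidationError
from otoseg.losses import LossConfig, composite_loss
from otoseg.model import NetworkConfig, build
from otoseg.nn import AdamW, Tensor
from otoseg.training import (
    ChunkSampler,
    TrainConfig,
    load_checkpoint,
    lr_at,
    make_folds,
    save_checkpoint,
    train_one_fold,
)


def _micro_net(seed=0, **kw):
    base = dict(levels=2, channels=(4, 8, 12), deep_supervision=False)
    base.update(kw)
    return build(NetworkConfig(seed=seed, **base))


def _tiny_cfg(**kw):
    base = dict(iterations=100, accumulation=2, lr=1e-3, validation_every=50,
                chunk=16, stride=16, augmentation="none", seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestLrSchedule:
    def test_trapezoid_endpoints_and_plateau(self):
        cfg = TrainConfig(iterations=1000, warmup_fraction=0.1,
                          plateau_fraction=0.6, lr=2e-3)
        assert lr_at(cfg, 0) == 0.0
        assert lr_at(cfg, 100) == 2e-3  # warmup complete
        assert lr_at(cfg, 500) == 2e-3  # mid-plateau
        # last iteration sits one step above zero on the anneal ramp
        assert lr_at(cfg, 999) == pytest.approx(2e-3 / 300)

    def test_out_of_range_rejected(self):
        cfg = TrainConfig(iterations=10)
        with pytest.raises(ValidationError):
            lr_at(cfg, 10)
        with pytest.raises(ValidationError):
            lr_at(cfg, -1)

    def test_integral_matches_trapezoid_area(self):
        cfg = TrainConfig(iterations=10_000, warmup_fraction=0.1,
                          plateau_fraction=0.6, lr=1e-3)
        total = sum(lr_at(cfg, i) for i in range(cfg.iterations))
        w, p, a = cfg.warmup_iters, cfg.plateau_iters, cfg.anneal_iters
        area = cfg.lr * (w / 2 + p + a / 2)
        assert total == pytest.approx(area, rel=1e-3)


class TestFolds:
    def test_38_5_split_of_43(self):
        plan = make_folds(range(43), k=3, n_val=5, seed=1)
        for tr, va in zip(plan.train_ids, plan.val_ids):
            assert len(tr) == 38 and len(va) == 5
            assert not set(tr) & set(va)
            assert set(tr) | set(va) == set(range(43))

    def test_deterministic_given_seed(self):
        a = make_folds(range(20), k=3, n_val=4, seed=9)
        b = make_folds(range(20), k=3, n_val=4, seed=9)
        assert a == b

    def test_excessive_validation_size_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(range(5), n_val=5)


class TestAccumulationEquivalence:
    def test_mean_accumulated_gradients_equal_large_batch(self, rng):
        # gradient linearity: stepping once with the mean of N per-sample
        # gradients equals stepping with the gradient of the mean loss
        samples = [rng.normal(size=(16, 16, 16)).astype(np.float32)
                   for _ in range(4)]
        labels = [(rng.random((16, 16, 16)) < 0.2).astype(np.float32)
                  for _ in range(4)]
        hms = [render(rng.uniform(0, 15, (3, 3)), (16, 16, 16), 1.0, 3.0)
               .astype(np.float32) for _ in range(4)]
        cfg = LossConfig()

        def run(mode):
            net = _micro_net(seed=21)
            opt = AdamW(net.parameters(), lr=1e-3, weight_decay=0.0)
            if mode == "accumulate":
                for x, y, h in zip(samples, labels, hms):
                    loss, _ = composite_loss(net(Tensor(x)), y[None], h, cfg)
                    loss.backward()
                for p in net.parameters():
                    p.grad /= 4.0
            else:  # one large batch: mean of the four losses
                total = None
                for x, y, h in zip(samples, labels, hms):
                    loss, _ = composite_loss(net(Tensor(x)), y[None], h, cfg)
                    total = loss if total is None else total + loss
                (total * 0.25).backward()
            opt.step()
            return np.concatenate([p.data.ravel() for p in net.parameters()])

        a, b = run("accumulate"), run("batch")
        np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-7)


class TestSampler:
    def test_deterministic_stream_without_augmentation(self, small_instances):
        cfg = _tiny_cfg(chunk=32, stride=25)
        sch = HeatmapSchedule().scaled(100)
        s1 = ChunkSampler(small_instances, cfg, sch)
        s2 = ChunkSampler(small_instances, cfg, sch)
        a, ta = s1.sample(0, np.random.default_rng(5))
        b, tb = s2.sample(0, np.random.default_rng(5))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(ta, tb)

    def test_target_max_equals_schedule_alpha(self, small_instances):
        cfg = _tiny_cfg(chunk=32, stride=25)
        sch = HeatmapSchedule(milestones=(0,), params=((2.5, 3.0),))
        sampler = ChunkSampler(small_instances, cfg, sch)
        rng = np.random.default_rng(0)
        found = False
        for _ in range(10):
            s, t = sampler.sample(0, rng)
            inb = ((s.landmarks >= 0) & (s.landmarks <= 31)).all(axis=1)
            if inb.any():
                assert t.max() == pytest.approx(2.5, rel=1e-3)
                found = True
        assert found

    def test_every_origin_sampled(self, small_instances):
        # coupon-collector style check over the chunk grid
        cfg = _tiny_cfg(chunk=16, stride=16)
        sch = HeatmapSchedule().scaled(100)
        sampler = ChunkSampler(small_instances[:1], cfg, sch)
        grid = sampler.grids[0]
        rng = np.random.default_rng(2)
        seen = set()
        for _ in range(400):
            idx = int(rng.integers(grid.n_chunks))
            seen.add(grid.origins[idx])
        assert seen == set(grid.origins)


class TestTrainLoop:
    def test_validation_cadence(self, small_instances):
        net = _micro_net(seed=1)
        cfg = _tiny_cfg(iterations=100, validation_every=50, chunk=16, stride=16)
        res = train_one_fold(net, small_instances[:2], small_instances[2:3],
                             cfg, LossConfig(), HeatmapSchedule().scaled(100))
        assert len(res.log) == 2
        assert [r["iteration"] for r in res.log] == [50, 100]

    def test_descent_smoke(self, small_instances):
        net = _micro_net(seed=3)
        cfg = _tiny_cfg(iterations=120, accumulation=2, lr=3e-3,
                        validation_every=40, chunk=16, stride=16)
        res = train_one_fold(net, small_instances[:2], small_instances[2:3],
                             cfg, LossConfig(), HeatmapSchedule().scaled(120))
        assert res.log[-1]["train_loss"] < res.log[0]["train_loss"]

    def test_full_run_reproducibility(self, small_instances):
        cfg = _tiny_cfg(iterations=40, validation_every=20, chunk=16, stride=16)
        sch = HeatmapSchedule().scaled(40)
        r1 = train_one_fold(_micro_net(seed=2), small_instances[:2],
                            small_instances[2:3], cfg, LossConfig(), sch)
        r2 = train_one_fold(_micro_net(seed=2), small_instances[:2],
                            small_instances[2:3], cfg, LossConfig(), sch)
        assert [a["dsc"] for a in r1.log] == [b["dsc"] for b in r2.log]
        for k in r1.last_state:
            np.testing.assert_array_equal(r1.last_state[k], r2.last_state[k])

    def test_best_checkpoint_tracks_max_dsc(self, small_instances):
        net = _micro_net(seed=4)
        cfg = _tiny_cfg(iterations=80, validation_every=20, chunk=16, stride=16)
        res = train_one_fold(net, small_instances[:2], small_instances[2:3],
                             cfg, LossConfig(), HeatmapSchedule().scaled(80))
        best_logged = max(r["dsc"] for r in res.log)
        assert res.best_dsc == pytest.approx(best_logged)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        net = _micro_net(seed=6)
        cfg = _tiny_cfg()
        p = tmp_path / "ck.npz"
        save_checkpoint(p, net.state_dict(), net.config, cfg)
        state, net_cfg, train_meta = load_checkpoint(p)
        assert net_cfg == net.config
        assert train_meta["chunk"] == cfg.chunk
        net2 = build(net_cfg)
        net2.load_state_dict(state)
        for (_, a), (_, b) in zip(net.named_parameters(), net2.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_mismatched_state_rejected(self, tmp_path):
        net = _micro_net(seed=6)
        other = _micro_net(seed=0, channels=(6, 8, 12))
        with pytest.raises(ValueError, match="mismatch|shape"):
            other.load_state_dict(net.state_dict())
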