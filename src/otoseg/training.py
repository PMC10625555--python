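"""Optimization loop: gradient accumulation, trapezoidal learning-rate
schedule, periodic validation, best/last checkpointing, and k-fold
cross-validation planning.

One *iteration* is the forward pass of one chunk, the loss computation and
the gradient computation; parameters are updated every ``accumulation``
iterations with the mean of the accumulated gradients, so the effective
step is invariant to the accumulation count. Every ``validation_every``
iterations the model is evaluated on the fold's validation instances
(segmentation DSC/IoU, heatmap MSE/MAE, validation loss) and the parameters
achieving the best validation DSC so far are snapshotted alongside the
final ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import Sample, apply_protocol, get_protocol
from .chunking import extract, plan_chunks
from .heatmap import HeatmapSchedule, render
from .io_core import LandmarkSet, ValidationError
from .losses import LossConfig, composite_loss
from .metrics import dsc as _dsc, iou as _iou
from .model import DualHeadUNet, PredictionBundle
from .nn import Tensor, make_optimizer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 75_000
    accumulation: int = 10
    optimizer: str = "adamw"
    lr: float = 1e-3
    weight_decay: float = 0.025
    adam_betas: tuple[float, float] = (0.9, 0.999)
    sgd_momentum: float = 0.9
    warmup_fraction: float = 0.1
    plateau_fraction: float = 0.6
    validation_every: int = 750
    folds: int = 3
    n_val: int = 5
    chunk: int = 128
    stride: int = 25
    augmentation: str = "alpha"
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1 or self.accumulation < 1 or self.validation_every < 1:
            raise ValidationError("iterations, accumulation, validation_every must be >= 1")
        if not 0 <= self.warmup_fraction and not 0 <= self.plateau_fraction:
            raise ValidationError("phase fractions must be non-negative")
        if self.warmup_fraction + self.plateau_fraction > 1.0 + 1e-9:
            raise ValidationError("warmup + plateau fractions must not exceed 1")

    @property
    def warmup_iters(self) -> int:
        return int(round(self.iterations * self.warmup_fraction))

    @property
    def plateau_iters(self) -> int:
        return int(round(self.iterations * self.plateau_fraction))

    @property
    def anneal_iters(self) -> int:
        return self.iterations - self.warmup_iters - self.plateau_iters


def lr_at(cfg: TrainConfig, iteration: int) -> float:
    """Trapezoidal schedule: linear warmup, constant plateau, linear anneal."""
    if not 0 <= iteration < cfg.iterations:
        raise ValidationError(
            f"iteration {iteration} outside [0, {cfg.iterations})"
        )
    w, p = cfg.warmup_iters, cfg.plateau_iters
    if iteration < w:
        return cfg.lr * iteration / w
    if iteration < w + p:
        return cfg.lr
    a = cfg.anneal_iters
    return cfg.lr * (cfg.iterations - iteration) / a


@dataclass(frozen=True)
class FoldPlan:
    k: int
    train_ids: tuple[tuple[int, ...], ...]
    val_ids: tuple[tuple[int, ...], ...]


def make_folds(instance_ids, k: int = 3, n_val: int = 5, seed: int = 0) -> FoldPlan:
    """Per fold, an independent seeded random split into train/validation.

    Each fold resamples its validation set from scratch (validation sets of
    different folds may overlap), mirroring a random-resample k-fold
    convention rather than a strict partition.
    """
    ids = list(instance_ids)
    if n_val >= len(ids):
        raise ValidationError(f"n_val={n_val} must be < number of instances {len(ids)}")
    rng = np.random.default_rng(seed)
    train_folds, val_folds = [], []
    for _ in range(k):
        perm = rng.permutation(len(ids))
        val = tuple(ids[i] for i in sorted(perm[:n_val]))
        train = tuple(ids[i] for i in sorted(perm[n_val:]))
        val_folds.append(val)
        train_folds.append(train)
    return FoldPlan(k=k, train_ids=tuple(train_folds), val_ids=tuple(val_folds))


# -- sampling --------------------------------------------------------------


class ChunkSampler:
    """Streams augmented training samples with rendered heatmap targets.

    Instances are (image, label, landmarks) triples of preprocessed arrays;
    chunks are drawn uniformly over (instance, grid origin), augmented per
    the protocol, and the target heatmap stack is rendered at the schedule's
    current (alpha, beta).
    """

    def __init__(self, instances, cfg: TrainConfig, schedule: HeatmapSchedule,
                 background: float = 0.0):
        if not instances:
            raise ValidationError("no training instances")
        self.instances = instances
        self.cfg = cfg
        self.schedule = schedule
        self.background = background
        self.protocol = get_protocol(cfg.augmentation)
        self.grids = [
            plan_chunks(img.shape, chunk=cfg.chunk, stride=cfg.stride)
            for img, _, _ in instances
        ]

    def sample(self, iteration: int, rng: np.random.Generator):
        """One (Sample, heatmap_target) pair for the given iteration."""
        idx = int(rng.integers(len(self.instances)))
        img, lab, lms = self.instances[idx]
        grid = self.grids[idx]
        origin = np.asarray(grid.origins[int(rng.integers(grid.n_chunks))])
        c = self.cfg.chunk
        sl = tuple(slice(o, o + c) for o in origin)
        coords = lms.as_array() if isinstance(lms, LandmarkSet) else np.asarray(lms)
        s = Sample(
            image=np.ascontiguousarray(img[sl], dtype=np.float32),
            label=np.ascontiguousarray(lab[sl]),
            landmarks=coords - origin,
            background=self.background,
        )
        s = apply_protocol(s, self.protocol, rng)
        alpha, beta = self.schedule.at(iteration)
        target = render(s.landmarks, s.image.shape, alpha, beta).astype(np.float32)
        return s, target


def _downsample_targets(seg: np.ndarray, landmarks: np.ndarray, alpha, beta,
                        n_aux: int):
    """Auxiliary targets for deep-supervision terminals t1..t_n.

    Labels are nearest-neighbor strided; heatmaps re-rendered at the reduced
    resolution with coordinates and spread scaled by the same factor.
    """
    out = []
    for i in range(1, n_aux + 1):
        f = 2**i
        seg_i = seg[::f, ::f, ::f]
        shape_i = seg_i.shape
        hm_i = render(landmarks / f, shape_i, alpha, max(beta / f, 0.5))
        out.append((seg_i, hm_i.astype(np.float32)))
    return out


# -- validation ------------------------------------------------------------


def evaluate_instance(net: DualHeadUNet, img: np.ndarray, lab: np.ndarray,
                      lms, cfg: TrainConfig, alpha: float, beta: float):
    """Chunked (no-TTA) prediction of one instance plus its metrics."""
    from .inference import predict_volume_raw  # local import to avoid a cycle

    seg_prob, hm = predict_volume_raw(net, img, chunk=cfg.chunk, stride=cfg.stride)
    out = {"dsc": 0.0, "iou": 0.0, "mse": 0.0, "mae": 0.0}
    if seg_prob is not None:
        truth = lab.astype(bool)
        out["dsc"] = _dsc(seg_prob >= 0.5, truth)
        out["iou"] = _iou(seg_prob >= 0.5, truth)
    if hm is not None:
        coords = lms.as_array() if isinstance(lms, LandmarkSet) else np.asarray(lms)
        diff = hm - render(coords, img.shape, alpha, beta)
        out["mse"] = float((diff**2).mean())
        out["mae"] = float(np.abs(diff).mean())
    return out


@dataclass
class TrainResult:
    best_state: dict
    last_state: dict
    best_iteration: int
    best_dsc: float
    log: list[dict]
    config: TrainConfig


def train_one_fold(
    net: DualHeadUNet,
    train_instances,
    val_instances,
    cfg: TrainConfig,
    loss_cfg: LossConfig | None = None,
    schedule: HeatmapSchedule | None = None,
    log_path: Path | None = None,
) -> TrainResult:
    """Run the optimization loop for one fold; fully seeded.

    ``*_instances``: lists of (image, label, landmarks) with preprocessed
    float32 images. Returns best- and last-iteration parameter snapshots and
    the validation log.
    """
    loss_cfg = loss_cfg or LossConfig()
    schedule = schedule or HeatmapSchedule().scaled(cfg.iterations)
    sampler = ChunkSampler(train_instances, cfg, schedule)
    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(
        cfg.optimizer, net.parameters(), lr=cfg.lr,
        weight_decay=cfg.weight_decay, betas=cfg.adam_betas,
        momentum=cfg.sgd_momentum,
    )
    n_aux = (net.config.levels - 1) if net.config.deep_supervision else 0

    best_dsc, best_iter = -1.0, -1
    best_state = net.state_dict()
    log: list[dict] = []
    accum = 0
    log_fh = open(log_path, "w") if log_path else None

    try:
        for it in range(cfg.iterations):
            sample, hm_target = sampler.sample(it, rng)
            alpha, beta = schedule.at(it)
            bundle = net(Tensor(sample.image))
            seg_t = sample.label.astype(np.float32)[None]
            aux_t = None
            if n_aux:
                aux_t = [
                    (s[None], h) for s, h in _downsample_targets(
                        sample.label.astype(np.float32), sample.landmarks,
                        alpha, beta, n_aux)
                ]
            total, comps = composite_loss(bundle, seg_t, hm_target, loss_cfg, aux_t)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it}: {comps}"
                )
            total.backward()
            accum += 1
            if accum == cfg.accumulation:
                inv = 1.0 / cfg.accumulation
                for p in net.parameters():
                    if p.grad is not None:
                        p.grad *= inv
                opt.lr = lr_at(cfg, it)
                opt.step()
                opt.zero_grad()
                accum = 0

            if (it + 1) % cfg.validation_every == 0 and val_instances:
                net.eval()
                rows = [
                    evaluate_instance(net, img, lab, lms, cfg, alpha, beta)
                    for img, lab, lms in val_instances
                ]
                net.train()
                rec = {
                    "iteration": it + 1,
                    "lr": lr_at(cfg, it),
                    "train_loss": comps["total"],
                    **{k: float(np.mean([r[k] for r in rows]))
                       for k in ("dsc", "iou", "mse", "mae")},
                }
                log.append(rec)
                if log_fh:
                    log_fh.write(json.dumps(rec) + "\n")
                    log_fh.flush()
                logger.info("it %d: val DSC %.4f IoU %.4f MSE %.4g",
                            rec["iteration"], rec["dsc"], rec["iou"], rec["mse"])
                if rec["dsc"] >= best_dsc:  # ties resolve to later iteration
                    best_dsc, best_iter = rec["dsc"], it + 1
                    best_state = net.state_dict()
    finally:
        if log_fh:
            log_fh.close()

    return TrainResult(
        best_state=best_state,
        last_state=net.state_dict(),
        best_iteration=best_iter,
        best_dsc=best_dsc,
        log=log,
        config=cfg,
    )


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(path, state: dict, net_config, train_config: TrainConfig | None = None):
    """Parameters + full configuration, .npz with a JSON sidecar field."""
    from dataclasses import asdict

    meta = {
        "network": asdict(net_config),
        "training": asdict(train_config) if train_config else None,
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path):
    """Returns (state_dict, network_config, train_config_dict_or_None)."""
    from .model import NetworkConfig

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    nc = meta["network"]
    nc["channels"] = tuple(nc["channels"])
    return state, NetworkConfig(**nc), meta.get("training")
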