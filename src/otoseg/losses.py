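"""Loss functions for the joint segmentation + heatmap-regression objective.

The composite objective is the unweighted sum of a segmentation term
(binary cross-entropy plus soft Dice by default) and the heatmap
mean-squared error, summed over the deep-supervision terminals with
per-terminal weights. The weight-decay regularizer is *not* part of the
returned loss — it is applied decoupled inside the AdamW/SGD step — so the
logged components reflect data fit only.

All functions accept either autodiff Tensors (training path) or plain
arrays (evaluation path) and return a Tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

SEG_LOSSES = ("ce_plus_dice", "dice", "squared_dice", "log_cosh_dice", "ce")

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    seg_loss: str = "ce_plus_dice"
    dice_smoothing: float = 1e-5
    heatmap_loss: str = "mse"
    # finest terminal first (t0, t1, ...); normalized to sum 1 at use
    deep_supervision_weights: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    weight_decay: float = 0.025  # applied by the optimizer, not the loss

    def __post_init__(self):
        if self.seg_loss not in SEG_LOSSES:
            raise ValueError(f"seg_loss must be one of {SEG_LOSSES}")
        if self.heatmap_loss != "mse":
            raise ValueError("only mse heatmap loss is implemented")
        if self.dice_smoothing <= 0:
            raise ValueError("dice smoothing must be positive")
        if not self.deep_supervision_weights or self.deep_supervision_weights[0] <= 0:
            raise ValueError("terminal t0 must carry positive weight")
        if any(w < 0 for w in self.deep_supervision_weights):
            raise ValueError("supervision weights must be non-negative")


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _check_shapes(pred: Tensor, target: Tensor):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")


def soft_dice_loss(pred, target, eps: float = 1e-5) -> Tensor:
    """1 - (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)."""
    pred, target = _t(pred), _t(target)
    _check_shapes(pred, target)
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def squared_dice_loss(pred, target, eps: float = 1e-5) -> Tensor:
    """Dice variant with squared terms in the denominator."""
    pred, target = _t(pred), _t(target)
    _check_shapes(pred, target)
    inter = (pred * target).sum()
    denom = (pred * pred).sum() + (target * target).sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def log_cosh_dice_loss(pred, target, eps: float = 1e-5) -> Tensor:
    """log(cosh(dice_loss)); a smoothed variant, always <= the Dice loss."""
    d = soft_dice_loss(pred, target, eps)
    # log cosh x = softplus(2x) - x - log 2, numerically stable
    return (2.0 * d).softplus() - d - float(np.log(2.0))


def cross_entropy_loss(pred, target) -> Tensor:
    """Voxel-mean binary cross-entropy; predictions clamped to (0, 1)."""
    pred, target = _t(pred), _t(target)
    _check_shapes(pred, target)
    p = pred.clip(_CLAMP, 1.0 - _CLAMP)
    return -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()


def heatmap_mse(pred, target) -> Tensor:
    """Mean over channels and voxels of the squared difference."""
    pred, target = _t(pred), _t(target)
    _check_shapes(pred, target)
    diff = pred - target
    return (diff * diff).mean()


def seg_loss_variant(name: str):
    """Return the segmentation loss callable for a configured variant."""
    if name == "ce_plus_dice":
        return lambda p, t, eps=1e-5: cross_entropy_loss(p, t) + soft_dice_loss(p, t, eps)
    if name == "dice":
        return lambda p, t, eps=1e-5: soft_dice_loss(p, t, eps)
    if name == "squared_dice":
        return lambda p, t, eps=1e-5: squared_dice_loss(p, t, eps)
    if name == "log_cosh_dice":
        return lambda p, t, eps=1e-5: log_cosh_dice_loss(p, t, eps)
    if name == "ce":
        return lambda p, t, eps=1e-5: cross_entropy_loss(p, t)
    raise ValueError(f"unknown segmentation loss {name!r}; choose from {SEG_LOSSES}")


def composite_loss(bundle, seg_target, heatmap_target, cfg: LossConfig,
                   aux_targets=None):
    """Total loss over all supervision terminals, with component breakdown.

    ``bundle``: a PredictionBundle; ``aux_targets``: list of (seg, heatmap)
    target pairs matching ``bundle.aux`` resolutions (required when deep
    supervision is active). Returns (total: Tensor, components: dict).
    """
    seg_fn = seg_loss_variant(cfg.seg_loss)
    eps = cfg.dice_smoothing
    w = np.asarray(cfg.deep_supervision_weights, dtype=float)

    terminals = [(bundle.seg, bundle.heatmaps,
                  None if seg_target is None else _t(seg_target),
                  None if heatmap_target is None else _t(heatmap_target))]
    if bundle.aux:
        if aux_targets is None or len(aux_targets) != len(bundle.aux):
            raise ValueError(
                "deep supervision is active but auxiliary targets are missing"
            )
        for (ps, ph), (ts, th) in zip(bundle.aux, aux_targets):
            terminals.append((ps, ph,
                              None if ts is None else _t(ts),
                              None if th is None else _t(th)))
    weights = w[: len(terminals)]
    weights = weights / weights.sum()

    total = None
    comp = {"seg": 0.0, "heatmap": 0.0}
    for wt, (ps, ph, ts, th) in zip(weights, terminals):
        term = None
        if ps is not None:  # segmentation head absent in heatmap-only nets
            ls = seg_fn(ps, ts, eps) * float(wt)
            comp["seg"] += ls.item()
            term = ls
        if ph is not None:
            lh = heatmap_mse(ph, th) * float(wt)
            comp["heatmap"] += lh.item()
            term = lh if term is None else term + lh
        if term is None:
            raise ValueError("prediction bundle carries no head outputs")
        total = term if total is None else total + term
    comp["total"] = total.item()
    return total, comp
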