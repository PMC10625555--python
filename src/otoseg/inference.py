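"""Full-volume prediction: chunking, rotational test-time augmentation with
voxel-wise uncertainty, mean aggregation, binarization and landmark
decoding.

The TTA plan is the identity plus quarter-turn rotations (90, 180, 270
degrees) about each of the three spatial axes: ten exactly invertible voxel
permutations in total. Per chunk, every transform is applied to the input,
the network forward-passed, and both heads' outputs inverse-rotated; the ten
segmentation supersamples yield a voxel-wise mean and population standard
deviation. The SD map, averaged over the volume, is the scalar
out-of-distribution signal: pathology or domain shift raises it by an order
of magnitude relative to in-distribution inputs.

Landmarks are decoded from the fully aggregated heatmap volume so the
argmax is global rather than per-chunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chunking import aggregate, pad_to_chunk, plan_chunks
from .heatmap import decode
from .io_core import LabelVolume, LandmarkSet, ValidationError, Volume
from .model import DualHeadUNet
from .nn import Tensor

_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclass(frozen=True)
class TTAPlan:
    """Identity + 9 quarter-turn rotations; all exactly invertible."""

    transforms: tuple[tuple[int, int], ...]  # (axis, quarter_turns); (-1,0)=identity

    @property
    def count(self) -> int:
        return len(self.transforms)


def tta_plan() -> TTAPlan:
    transforms = [(-1, 0)]
    transforms += [(axis, k) for axis in (0, 1, 2) for k in (1, 2, 3)]
    return TTAPlan(transforms=tuple(transforms))


def _rot(data: np.ndarray, axis: int, k: int) -> np.ndarray:
    """Rotate the trailing three axes; leading channel axes untouched."""
    if axis < 0 or k % 4 == 0:
        return data
    a, b = _PLANES[axis]
    off = data.ndim - 3
    return np.rot90(data, k, axes=(a + off, b + off))


def _inv_rot(data: np.ndarray, axis: int, k: int) -> np.ndarray:
    return _rot(data, axis, -k % 4 if axis >= 0 else 0)


@dataclass
class UncertaintyMap:
    """Per-voxel TTA supersample standard deviations (population, ddof=0)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if (self.data < 0).any():
            raise ValidationError("standard deviations must be non-negative")

    @property
    def summary(self) -> float:
        return float(self.data.mean())


def uncertainty_summary(u: UncertaintyMap | None) -> float:
    """Volume-mean of the per-voxel TTA standard deviation."""
    if u is None:
        raise ValidationError("uncertainty summary requires TTA (>= 2 supersamples)")
    return u.summary


def sd_fold_change(sd_ood: float, sd_reference: float) -> float:
    """Ratio of out-of-distribution to reference volume-mean TTA SD."""
    if sd_reference <= 0:
        raise ValidationError("reference SD must be positive")
    return sd_ood / sd_reference


def supersample_sd(stack: np.ndarray) -> np.ndarray:
    """Per-voxel population SD over TTA supersamples.

    Computed in float64; voxels where all supersamples agree bitwise are
    exactly zero (floating-point dust from the mean subtraction is removed).
    """
    sd = stack.astype(np.float64).std(axis=0, ddof=0)
    sd[np.ptp(stack, axis=0) == 0] = 0.0
    return sd


def predict_chunk_tta(net, chunk: np.ndarray, plan: TTAPlan):
    """(mean seg, mean heatmaps, seg supersample stack) for one chunk.

    ``net`` is any callable returning an object with ``seg`` (1, D, H, W)
    and ``heatmaps`` (3, D, H, W) attributes (Tensor or ndarray).
    """
    seg_stack, hm_sum = [], None
    for axis, k in plan.transforms:
        x = np.ascontiguousarray(_rot(chunk, axis, k))
        bundle = net(x)
        seg = _unwrap(bundle.seg)
        hm = _unwrap(bundle.heatmaps)
        if seg is not None:
            seg_stack.append(_inv_rot(seg[0], axis, k))
        if hm is not None:
            hm_inv = _inv_rot(hm, axis, k)
            hm_sum = hm_inv.copy() if hm_sum is None else hm_sum + hm_inv
    stack = np.stack(seg_stack) if seg_stack else None  # (N_TTA, D, H, W)
    seg_mean = None if stack is None else stack.mean(axis=0)
    hm_mean = None if hm_sum is None else hm_sum / plan.count
    return seg_mean, hm_mean, stack


def _unwrap(x):
    if x is None:
        return None
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _forward_plain(net, chunk: np.ndarray):
    bundle = net(chunk)
    seg = _unwrap(bundle.seg)
    hm = _unwrap(bundle.heatmaps)
    return (None if seg is None else seg[0]), hm


def predict_volume_raw(net, image: np.ndarray, chunk: int = 128,
                       stride: int = 25):
    """Chunked no-TTA prediction: (seg probability map, heatmap volume)."""
    padded, crop = pad_to_chunk(image, chunk)
    grid = plan_chunks(padded.shape, chunk=chunk, stride=stride)
    seg_chunks, hm_chunks = [], []
    cz, cy, cx = grid.chunk_shape
    for oz, oy, ox in grid.origins:
        sub = np.ascontiguousarray(padded[oz:oz + cz, oy:oy + cy, ox:ox + cx])
        seg, hm = _forward_plain(net, sub)
        seg_chunks.append(seg)
        hm_chunks.append(hm)
    seg_full = None if seg_chunks[0] is None else aggregate(seg_chunks, grid)[crop]
    hm_full = (None if hm_chunks[0] is None
               else aggregate(hm_chunks, grid)[(slice(None), *crop)])
    return seg_full, hm_full


@dataclass
class VolumePrediction:
    label: LabelVolume | None
    landmarks: LandmarkSet | None
    probability: np.ndarray | None
    heatmaps: np.ndarray | None
    uncertainty: UncertaintyMap | None


def predict_volume(
    net: DualHeadUNet | object,
    vol: Volume,
    chunk: int = 128,
    stride: int = 25,
    tta: bool = True,
    threshold: float = 0.5,
) -> VolumePrediction:
    """End-to-end prediction for one (already preprocessed) volume.

    Chunks the volume, runs per-chunk TTA (optional), fuses probabilities,
    heatmaps and TTA-SD maps across chunks by voxel mean, binarizes the
    probability map at ``threshold`` and decodes landmarks from the
    aggregated heatmap volume.
    """
    if hasattr(net, "eval"):
        net.eval()
    image = np.asarray(vol.data, dtype=np.float32)
    padded, crop = pad_to_chunk(image, chunk)
    grid = plan_chunks(padded.shape, chunk=chunk, stride=stride)
    plan = tta_plan() if tta else None

    seg_chunks, hm_chunks, sd_chunks = [], [], []
    cz, cy, cx = grid.chunk_shape
    for oz, oy, ox in grid.origins:
        sub = np.ascontiguousarray(padded[oz:oz + cz, oy:oy + cy, ox:ox + cx])
        if plan is not None:
            seg_mean, hm_mean, stack = predict_chunk_tta(net, sub, plan)
            if stack is not None:
                sd_chunks.append(supersample_sd(stack))
        else:
            seg_mean, hm_mean = _forward_plain(net, sub)
        seg_chunks.append(seg_mean)
        hm_chunks.append(hm_mean)

    prob = None if seg_chunks[0] is None else aggregate(seg_chunks, grid)[crop]
    heat = (None if hm_chunks[0] is None
            else aggregate(hm_chunks, grid)[(slice(None), *crop)])
    for arr in (prob, heat):
        if arr is not None and not np.isfinite(arr).all():
            raise FloatingPointError("non-finite values in aggregated prediction")
    uncertainty = None
    if plan is not None and sd_chunks:
        sd_full = aggregate(sd_chunks, grid)[crop]
        uncertainty = UncertaintyMap(data=sd_full)

    label = None
    if prob is not None:
        label = LabelVolume(
            data=(prob >= threshold).astype(np.uint8),
            spacing=vol.spacing,
            origin=vol.origin,
        )
    return VolumePrediction(
        label=label,
        landmarks=None if heat is None else decode(heat),
        probability=prob,
        heatmaps=heat,
        uncertainty=uncertainty,
    )
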