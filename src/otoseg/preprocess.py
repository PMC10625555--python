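"""Intensity normalization: quantile clipping, z-normalization, and
cluster-wise histogram matching for domain-shifted inputs.

The training-domain pipeline is ``clip_quantiles`` followed by
``znormalize``. External (domain-shifted) volumes additionally pass through
``histogram_match`` against a reference quantile table computed once from
the training cohort; for inputs whose intensity range splits into distinct
acquisition clusters the whole chain runs per cluster
(:func:`preprocess_external`).

Conventions fixed here: quantiles use linear interpolation between order
statistics; the standard deviation is the population (ddof=0) value;
histogram matching uses 256 quantile levels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import ValidationError, Volume

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 256


class NormalizationError(ValueError):
    pass


@dataclass
class IntensityStats:
    """Parameters of a normalization run plus the reference distribution."""

    q_low: float = 0.01
    q_high: float = 0.99
    clip_low: float = 0.0
    clip_high: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    reference_quantiles: np.ndarray | None = None  # (levels, 2): level, value

    def __post_init__(self):
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValidationError("need 0 <= q_low < q_high <= 1")
        if self.reference_quantiles is not None:
            self.reference_quantiles = validate_reference(self.reference_quantiles)


def validate_reference(ref) -> np.ndarray:
    ref = np.asarray(ref, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 2:
        raise ValidationError("reference quantile table must be (n>=2, 2)")
    if (np.diff(ref[:, 0]) < 0).any() or (np.diff(ref[:, 1]) < -1e-12).any():
        raise ValidationError("reference quantile table must be non-decreasing")
    return ref


def clip_quantiles(vol: Volume, q_low: float = 0.01, q_high: float = 0.99) -> Volume:
    """Clip intensities to the empirical [q_low, q_high] quantile interval."""
    if not 0 <= q_low < q_high <= 1:
        raise ValidationError("need 0 <= q_low < q_high <= 1")
    lo, hi = np.quantile(vol.data, [q_low, q_high])
    return Volume(
        data=np.clip(vol.data, lo, hi), spacing=vol.spacing, origin=vol.origin
    )


def znormalize(vol: Volume) -> tuple[Volume, IntensityStats]:
    """Shift/scale to zero mean and unit (population) standard deviation."""
    mu = float(vol.data.mean())
    sd = float(vol.data.std())
    if sd == 0:
        raise NormalizationError("constant volume cannot be z-normalized (sd = 0)")
    out = Volume(
        data=((vol.data - mu) / sd).astype(np.float32),
        spacing=vol.spacing,
        origin=vol.origin,
    )
    return out, IntensityStats(mean=mu, sd=sd)


def reference_from_volumes(
    volumes, levels: int = DEFAULT_LEVELS, preprocessed: bool = False
) -> np.ndarray:
    """Quantile table of the training-domain distribution.

    Each volume is clipped and z-normalized first (unless ``preprocessed``),
    then the pooled voxels' quantiles at ``levels`` evenly spaced levels are
    tabulated.
    """
    pooled = []
    for v in volumes:
        if not preprocessed:
            v, _ = znormalize(clip_quantiles(v))
        pooled.append(v.data.ravel())
    pooled = np.concatenate(pooled)
    lv = np.linspace(0.0, 1.0, levels)
    return np.stack([lv, np.quantile(pooled, lv)], axis=1)


def save_reference(ref: np.ndarray, path) -> Path:
    path = Path(path)
    ref = validate_reference(ref)
    path.write_text(json.dumps({"levels": ref[:, 0].tolist(),
                                "values": ref[:, 1].tolist()}))
    return path


def load_reference(path) -> np.ndarray:
    raw = json.loads(Path(path).read_text())
    return validate_reference(np.stack([raw["levels"], raw["values"]], axis=1))


def histogram_match(vol: Volume, ref) -> Volume:
    """Monotone quantile mapping of the input distribution onto ``ref``.

    A voxel at input quantile level p is mapped to the reference value at
    level p (linear interpolation between table rows). The mapping is
    non-decreasing, hence rank-preserving.
    """
    ref = validate_reference(ref)
    levels = ref[:, 0]
    src = np.quantile(vol.data, levels)
    flat = vol.data.ravel()
    # np.interp requires strictly increasing xp; collapse flat stretches
    keep = np.concatenate([[True], np.diff(src) > 0])
    out = np.interp(flat, src[keep], ref[keep, 1])
    return Volume(
        data=out.reshape(vol.data.shape).astype(np.float32),
        spacing=vol.spacing,
        origin=vol.origin,
    )


def preprocess_internal(vol: Volume, q_low: float = 0.01, q_high: float = 0.99):
    """Training-domain chain: clip then z-normalize."""
    return znormalize(clip_quantiles(vol, q_low, q_high))


def _chain_external(vol: Volume, ref, q_low, q_high) -> Volume:
    clipped = clip_quantiles(vol, q_low, q_high)
    matched = histogram_match(clipped, ref)
    return matched


def preprocess_external(
    vol: Volume,
    ref,
    cluster_bounds: list[float] | None = None,
    q_low: float = 0.01,
    q_high: float = 0.99,
) -> Volume:
    """Domain-shift correction: per-cluster clip + histogram match, then a
    final global z-normalization polish.

    ``cluster_bounds`` are intensity thresholds partitioning the observed
    range into acquisition clusters (user-supplied; the pipeline does not
    discover clusters automatically). With no bounds the whole volume is a
    single cluster and the chain reduces to the global case.
    """
    ref = validate_reference(ref)
    bounds = sorted(cluster_bounds or [])
    edges = [-np.inf, *bounds, np.inf]
    out = np.empty(vol.data.shape, dtype=np.float32)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (vol.data >= lo) & (vol.data < hi)
        n = int(mask.sum())
        if n == 0:
            logger.warning("empty intensity cluster [%s, %s) skipped", lo, hi)
            continue
        sub = Volume(
            data=vol.data[mask].reshape(n, 1, 1), spacing=vol.spacing
        )
        out[mask] = _chain_external(sub, ref, q_low, q_high).data.ravel()
    matched = Volume(data=out, spacing=vol.spacing, origin=vol.origin)
    normed, _ = znormalize(matched)
    return normed
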