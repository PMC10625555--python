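"""Gaussian heatmap targets for landmark regression, their training-time
(amplitude, spread) schedule, and argmax decoding.

A landmark at (possibly fractional) voxel coordinate c is encoded on the
chunk grid as ``alpha * exp(-||x - c||^2 / (2 beta^2))`` — ``beta`` plays the
role of a standard deviation in voxel units. Over training, a schedule makes
the target progressively sharper and taller: the amplitude sequence is
non-decreasing and the spread sequence non-increasing across its iteration
milestones (piecewise-constant, right-continuous lookup).

Decoding is the argmax voxel per channel, ties broken toward the
lexicographically smallest index. No sub-voxel refinement is applied, so a
decoded coordinate is always integral.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .io_core import LANDMARK_NAMES, LandmarkSet, ValidationError

logger = logging.getLogger(__name__)

#: Default schedule ("gamma"): milestones at 0%, 20% and 50% of the full
#: 75k-iteration run; amplitude rises 1 -> 5 -> 10 while the spread tightens
#: 6 -> 4 -> 2 voxels.
DEFAULT_MILESTONES = (0, 15_000, 37_500)
DEFAULT_PARAMS = ((1.0, 6.0), (5.0, 4.0), (10.0, 2.0))


@dataclass(frozen=True)
class HeatmapSchedule:
    milestones: tuple[int, ...] = DEFAULT_MILESTONES
    params: tuple[tuple[float, float], ...] = DEFAULT_PARAMS
    name: str = "gamma"

    def __post_init__(self):
        if len(self.milestones) != len(self.params) or not self.milestones:
            raise ValidationError("milestones and params must align and be non-empty")
        if self.milestones[0] != 0:
            raise ValidationError("first milestone must be iteration 0")
        if any(b <= a for a, b in zip(self.milestones, self.milestones[1:])):
            raise ValidationError("milestones must be strictly increasing")
        alphas = [p[0] for p in self.params]
        betas = [p[1] for p in self.params]
        if any(b <= 0 for b in betas):
            raise ValidationError("spread beta must be positive")
        if any(a2 < a1 for a1, a2 in zip(alphas, alphas[1:])):
            raise ValidationError("amplitude alpha must be non-decreasing")
        if any(b2 > b1 for b1, b2 in zip(betas, betas[1:])):
            raise ValidationError("spread beta must be non-increasing")

    def at(self, iteration: int) -> tuple[float, float]:
        """(alpha, beta) in force at ``iteration``; right-continuous steps."""
        if iteration < 0:
            raise ValidationError("iteration must be >= 0")
        idx = bisect_right(self.milestones, iteration) - 1
        return self.params[max(idx, 0)]

    def scaled(self, total_iterations: int) -> "HeatmapSchedule":
        """Rescale milestones proportionally to a shorter/longer run."""
        full = 75_000
        ms = tuple(
            int(round(m * total_iterations / full)) for m in self.milestones
        )
        # enforce strict increase after rounding
        fixed = [ms[0]]
        for m in ms[1:]:
            fixed.append(max(m, fixed[-1] + 1))
        return HeatmapSchedule(tuple(fixed), self.params, self.name)


def schedule_at(schedule: HeatmapSchedule, iteration: int) -> tuple[float, float]:
    return schedule.at(iteration)


def render(
    landmarks: LandmarkSet | np.ndarray,
    shape: tuple[int, int, int],
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Render the 3-channel Gaussian heatmap stack for ``landmarks``.

    Landmarks outside ``shape`` simply contribute their off-grid Gaussian
    tail (possibly all-zero), not an error — chunks far from a landmark have
    near-zero targets.
    """
    if alpha <= 0 or beta <= 0:
        raise ValidationError("alpha and beta must be positive")
    coords = (
        landmarks.as_array() if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks)
    )
    if coords.shape != (3, 3):
        raise ValidationError(f"expected 3 landmarks x 3 coords, got {coords.shape}")
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    stack = np.empty((3, *shape), dtype=np.float64)
    inv = 1.0 / (2.0 * beta * beta)
    for k, c in enumerate(coords):
        d2 = (
            ((axes[0] - c[0]) ** 2)[:, None, None]
            + ((axes[1] - c[1]) ** 2)[None, :, None]
            + ((axes[2] - c[2]) ** 2)[None, None, :]
        )
        stack[k] = alpha * np.exp(-d2 * inv)
    return stack


def decode(heatmaps: np.ndarray) -> LandmarkSet:
    """Argmax voxel per channel (ties -> lexicographically smallest index)."""
    hm = np.asarray(heatmaps)
    if hm.ndim != 4 or hm.shape[0] != 3:
        raise ValidationError(f"expected (3, D, H, W) heatmaps, got {hm.shape}")
    if not np.isfinite(hm).all():
        raise ValidationError("heatmaps contain non-finite values")
    coords = {}
    for k, name in enumerate(LANDMARK_NAMES):
        ch = hm[k]
        if ch.max() == ch.min():
            logger.warning("constant heatmap channel %s; decoding to origin", name)
            coords[name] = np.zeros(3)
            continue
        coords[name] = np.array(np.unravel_index(np.argmax(ch), ch.shape), dtype=float)
    return LandmarkSet(**coords)
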