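"""Training-time augmentation applied consistently to a chunk's intensities,
labels and landmark coordinates.

Two named protocols are provided. ``alpha`` uses fixed quarter-turn
rotations about the first volume axis only plus free-angle rotations with a
30 degree amplitude; ``beta`` extends fixed rotations to all three axes and
widens the free-angle amplitude to 45 degrees. Both may also rescale
contrast multiplicatively and add Gaussian or Poisson noise. Per-transform
application probabilities default to 0.5 and are configurable.

Spatial transforms act on the geometry and the landmark coordinates with the
same operator: fixed rotations are exact voxel permutations (and exactly
invertible); free rotations interpolate intensities trilinearly, labels
nearest-neighbor, and map landmarks with the exact rotation matrix about the
chunk center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_core import ValidationError


@dataclass
class Sample:
    """One training example: a chunk with its targets."""

    image: np.ndarray  # (D, H, W) float
    label: np.ndarray  # (D, H, W) {0,1}
    landmarks: np.ndarray  # (3, 3) voxel coords in chunk frame (may be out of bounds)
    background: float = 0.0  # fill value for out-of-bounds regions

    def copy(self) -> "Sample":
        return Sample(self.image.copy(), self.label.copy(),
                      self.landmarks.copy(), self.background)


@dataclass(frozen=True)
class AugmentationProtocol:
    name: str = "alpha"
    fixed_rotation_axes: tuple[int, ...] = (0,)
    free_rotation_amplitude: float = 30.0
    intensity_scale_range: tuple[float, float] = (0.85, 1.15)
    gaussian_noise_sigma: float = 0.08
    poisson_noise: bool = True
    poisson_lambda: float = 60.0
    p_fixed_rotation: float = 0.5
    p_free_rotation: float = 0.5
    p_scale: float = 0.5
    p_noise: float = 0.5

    def __post_init__(self):
        if self.free_rotation_amplitude < 0:
            raise ValidationError("rotation amplitude must be >= 0")
        if not 0 < self.intensity_scale_range[0] <= self.intensity_scale_range[1]:
            raise ValidationError("scale range must be positive and ordered")
        for p in (self.p_fixed_rotation, self.p_free_rotation, self.p_scale, self.p_noise):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")


PROTOCOLS = {
    "none": None,
    "alpha": AugmentationProtocol(name="alpha", fixed_rotation_axes=(0,),
                                  free_rotation_amplitude=30.0),
    "beta": AugmentationProtocol(name="beta", fixed_rotation_axes=(0, 1, 2),
                                 free_rotation_amplitude=45.0),
}


def get_protocol(name: str) -> AugmentationProtocol | None:
    if name not in PROTOCOLS:
        raise ValidationError(f"unknown augmentation protocol {name!r}")
    return PROTOCOLS[name]


# -- spatial transforms ----------------------------------------------------

_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def _rotate_coords_90(coords: np.ndarray, axis: int, k: int, shape) -> np.ndarray:
    """Map coordinates under ``np.rot90(vol, k, axes=_PLANES[axis])``.

    For one quarter turn with axes (a, b): new_a = (N_b - 1) - old_b,
    new_b = old_a. Applied k times.
    """
    a, b = _PLANES[axis]
    out = coords.astype(float).copy()
    n = list(shape)
    for _ in range(k % 4):
        na, nb = n[a], n[b]
        new_a = (nb - 1) - out[..., b]
        new_b = out[..., a].copy()
        out[..., a], out[..., b] = new_a, new_b
        n[a], n[b] = nb, na
    return out


def fixed_rotation(sample: Sample, axis: int, k: int) -> Sample:
    """Quarter-turn rotation (k in {1,2,3}) — a pure voxel permutation."""
    if k not in (1, 2, 3):
        raise ValidationError("k must be 1, 2 or 3 quarter turns")
    a, b = _PLANES[axis]
    if sample.image.shape[a] != sample.image.shape[b]:
        raise ValidationError(
            f"in-plane axes {a},{b} unequal ({sample.image.shape}); "
            "fixed rotations need matching extents"
        )
    return Sample(
        image=np.ascontiguousarray(np.rot90(sample.image, k, axes=(a, b))),
        label=np.ascontiguousarray(np.rot90(sample.label, k, axes=(a, b))),
        landmarks=_rotate_coords_90(sample.landmarks, axis, k, sample.image.shape),
        background=sample.background,
    )


def _rotation_matrix(axis: int, angle_deg: float) -> np.ndarray:
    """Rotation in the plane ``_PLANES[axis]`` matching scipy's convention."""
    a, b = _PLANES[axis]
    th = np.deg2rad(angle_deg)
    m = np.eye(3)
    m[a, a] = np.cos(th)
    m[a, b] = -np.sin(th)
    m[b, a] = np.sin(th)
    m[b, b] = np.cos(th)
    return m


def free_rotation(sample: Sample, axis: int, angle_deg: float) -> Sample:
    """Free-angle rotation about a coordinate axis through the chunk center."""
    a, b = _PLANES[axis]
    img = ndimage.rotate(
        sample.image, angle_deg, axes=(a, b), reshape=False, order=1,
        mode="constant", cval=sample.background,
    )
    lab = ndimage.rotate(
        sample.label, angle_deg, axes=(a, b), reshape=False, order=0,
        mode="constant", cval=0,
    )
    center = (np.asarray(sample.image.shape) - 1) / 2.0
    # scipy.ndimage.rotate maps output coords through the inverse matrix;
    # forward landmark transport therefore uses the transposed matrix
    m = _rotation_matrix(axis, angle_deg)
    lms = (sample.landmarks - center) @ m.T + center
    return Sample(image=img, label=lab.astype(sample.label.dtype),
                  landmarks=lms, background=sample.background)


# -- intensity transforms --------------------------------------------------


def intensity_augment(
    sample: Sample,
    scale: float = 1.0,
    gaussian_sigma: float = 0.0,
    poisson_lambda: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sample:
    """Contrast scaling and additive Gaussian or Poisson noise.

    Poisson noise is applied by shifting the (possibly z-normalized,
    negative) intensities to a positive range, sampling counts at rate
    ``poisson_lambda`` per unit intensity, and shifting back.
    """
    img = sample.image.astype(np.float32) * np.float32(scale)
    if gaussian_sigma > 0:
        if rng is None:
            raise ValidationError("noise requires an rng")
        img = img + rng.normal(0.0, gaussian_sigma, img.shape).astype(np.float32)
    if poisson_lambda > 0:
        if rng is None:
            raise ValidationError("noise requires an rng")
        shift = float(img.min()) - 1.0
        pos = (img - shift) * poisson_lambda
        img = (rng.poisson(pos) / poisson_lambda + shift).astype(np.float32)
    return Sample(image=img, label=sample.label, landmarks=sample.landmarks,
                  background=sample.background)


def apply_protocol(
    sample: Sample, protocol: AugmentationProtocol | str | None,
    rng: np.random.Generator,
) -> Sample:
    """Draw and apply one stochastic augmentation per the protocol."""
    if isinstance(protocol, str):
        protocol = get_protocol(protocol)
    if protocol is None:
        return sample
    out = sample
    if rng.random() < protocol.p_fixed_rotation:
        axis = int(rng.choice(protocol.fixed_rotation_axes))
        k = int(rng.integers(1, 4))
        out = fixed_rotation(out, axis, k)
    if rng.random() < protocol.p_free_rotation and protocol.free_rotation_amplitude > 0:
        axis = int(rng.integers(0, 3))
        angle = float(rng.uniform(-protocol.free_rotation_amplitude,
                                  protocol.free_rotation_amplitude))
        out = free_rotation(out, axis, angle)
    scale = 1.0
    if rng.random() < protocol.p_scale:
        scale = float(rng.uniform(*protocol.intensity_scale_range))
    sigma = 0.0
    lam = 0.0
    if rng.random() < protocol.p_noise:
        if protocol.poisson_noise and rng.random() < 0.5:
            lam = protocol.poisson_lambda
        else:
            sigma = protocol.gaussian_noise_sigma
    if scale != 1.0 or sigma > 0 or lam > 0:
        out = intensity_augment(out, scale, sigma, lam, rng)
    return out
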