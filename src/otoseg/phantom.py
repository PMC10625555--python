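"""Synthetic cochlea-like phantoms with ground-truth labels and landmarks.

The phantom is a geometric stand-in for the inner-ear labyrinth: the
segmentation foreground is the union of

* a conical spiral tube (cochlea analog) whose winding radius shrinks
  linearly with the turn parameter,
* three mutually orthogonal tori arcs (semicircular canal analogs), and
* an ellipsoid (vestibule analog) joining the spiral base to the canals.

Landmarks: the *helicotrema* analog is the spiral's apical endpoint; the
*oval window* and *round window* analogs are the centers of two small disc
patches on the vestibule boundary. Intensities form a two-phase image
(radiodense bone background, darker fluid-like foreground) plus additive
Gaussian noise. A rigid rotation can be applied to geometry and landmarks
jointly (curves are rotated before rasterization, so labels stay exact).

The generator is fully determined by its seed and is the test bed for every
downstream stage; it makes no claim to anatomical realism beyond the
structural features the pipeline exercises (thin curved tube, landmark at a
geometric extremum, boundary membranes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .io_core import LabelVolume, LandmarkSet, ValidationError, Volume

DOMAIN_SHIFTS = ("none", "invert_fluid", "offset_cluster")


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance parameters of one phantom instance.

    Defaults describe a 64-voxel cube at the pipeline's working spacing of
    99 µm; radii are in voxel units.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 99.0
    turns: float = 2.5
    spiral_radius_start: float = 11.0
    spiral_radius_end: float = 3.0
    spiral_height: float = 14.0
    tube_radius: float = 2.6
    canal_radii: tuple[float, float, float] = (6.5, 7.0, 7.5)
    canal_tube_radius: float = 1.6
    vestibule_radii: tuple[float, float, float] = (4.5, 3.5, 3.5)
    intensity_bg: float = 1800.0
    intensity_fg: float = 300.0
    noise_sigma: float = 60.0
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    domain_shift: str = "none"
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 8:
            raise ValidationError("phantom shape too small")
        for r in (self.spiral_radius_start, self.spiral_radius_end,
                  self.tube_radius, self.canal_tube_radius, *self.canal_radii,
                  *self.vestibule_radii):
            if r <= 0:
                raise ValidationError("all radii must be positive")
        if self.turns <= 0:
            raise ValidationError("turns must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if self.domain_shift not in DOMAIN_SHIFTS:
            raise ValidationError(f"domain_shift must be one of {DOMAIN_SHIFTS}")


def _spiral_curve(spec: PhantomSpec, n_samples: int = 600) -> np.ndarray:
    """Points of the conical spiral in centered coordinates (voxel units).

    Axis 0 is the spiral axis; radius decreases linearly from
    ``spiral_radius_start`` at t=0 (base) to ``spiral_radius_end`` at the
    apical end.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    theta = 2.0 * np.pi * spec.turns * t
    radius = spec.spiral_radius_start + t * (
        spec.spiral_radius_end - spec.spiral_radius_start
    )
    z = (t - 0.5) * spec.spiral_height
    return np.stack([z, radius * np.cos(theta), radius * np.sin(theta)], axis=1)


def _canal_curves(spec: PhantomSpec, attach: np.ndarray) -> list[np.ndarray]:
    """Three circular arcs in orthogonal planes, offset from the vestibule."""
    curves = []
    phi = np.linspace(0.0, 2.0 * np.pi, 200, endpoint=False)
    planes = [((1, 2), 0), ((0, 2), 1), ((0, 1), 2)]
    for (a, b), n, r in ((p, n, r) for (p, n), r in zip(planes, spec.canal_radii)):
        pts = np.zeros((phi.size, 3))
        pts[:, a] = r * np.cos(phi)
        pts[:, b] = r * np.sin(phi)
        pts[:, n] = 0.0
        curves.append(pts + attach)
    return curves


def _rasterize_tube(points: np.ndarray, radius: float, shape) -> np.ndarray:
    """Voxels within ``radius`` of the (already shifted) curve points."""
    grid = np.zeros(shape, dtype=bool)
    idx = np.round(points).astype(int)
    valid = ((idx >= 0) & (idx < np.asarray(shape))).all(axis=1)
    idx = idx[valid]
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not grid.any():
        return grid
    dist = ndimage.distance_transform_edt(~grid)
    return dist <= radius


def generate_phantom(spec: PhantomSpec):
    """Build (Volume, LabelVolume, LandmarkSet) from a spec; seeded."""
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    rot = Rotation.from_euler("xyz", spec.rotation, degrees=True)

    def place(pts):
        return rot.apply(pts) + center

    spiral = _spiral_curve(spec)
    base_pt, apex_pt = spiral[0], spiral[-1]
    # vestibule sits slightly above and inward of the spiral base; the canal
    # rings are offset further along the spiral axis so everything stays
    # within the margin even under the cohort's rotation jitter
    vest_center = base_pt + np.array(
        [3.0, -0.25 * spec.spiral_radius_start, 0.0]
    )
    canal_attach = vest_center + np.array([0.6 * max(spec.canal_radii), 0.0, 0.0])

    spiral_w = place(spiral)
    canals_w = [place(c) for c in _canal_curves(spec, canal_attach)]
    vest_center_w = place(vest_center[None])[0]

    fg = _rasterize_tube(spiral_w, spec.tube_radius, spec.shape)
    for c in canals_w:
        fg |= _rasterize_tube(c, spec.canal_tube_radius, spec.shape)

    # ellipsoidal vestibule, axes aligned with the rotated frame
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij"), axis=-1
    ).astype(float)
    rel = (coords - vest_center_w) @ rot.as_matrix()  # back to canonical frame
    radii = np.asarray(spec.vestibule_radii)
    fg |= ((rel / radii) ** 2).sum(axis=-1) <= 1.0

    # margin check: foreground must keep a 2-voxel border clear
    border = np.zeros(spec.shape, dtype=bool)
    border[:2], border[-2:], border[:, :2], border[:, -2:] = True, True, True, True
    border[:, :, :2] = border[:, :, -2:] = True
    if (fg & border).any():
        raise GeometryError(
            "phantom foreground violates the 2-voxel margin; shrink radii or rotation"
        )

    # landmarks: spiral apex; two window patches on the vestibule boundary
    helicotrema = spiral_w[-1]
    window_dirs = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    windows = []
    for d in window_dirs:
        surf = vest_center + d * radii  # canonical frame
        windows.append(place(surf[None])[0])
    oval_w, round_w = windows

    landmarks = LandmarkSet(
        helicotrema=np.round(helicotrema),
        oval_window=np.round(oval_w),
        round_window=np.round(round_w),
    )
    landmarks.validate_bounds(spec.shape)

    intens = np.full(spec.shape, spec.intensity_bg, dtype=np.float32)
    intens[fg] = spec.intensity_fg
    if spec.noise_sigma > 0:
        intens += rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    vol = Volume(data=intens, spacing=(spec.spacing,) * 3)
    if spec.domain_shift != "none":
        vol = apply_domain_shift(vol, spec.domain_shift)
    label = LabelVolume(data=fg.astype(np.uint8), spacing=(spec.spacing,) * 3)
    return vol, label, landmarks


def apply_domain_shift(vol: Volume, mode: str, offset: float = 500.0) -> Volume:
    """Emulate acquisition/preservation-induced contrast shifts.

    ``invert_fluid`` reflects intensities about the volume's mid-range,
    swapping the foreground/background contrast ordering (dry or embalmed
    specimen analog). ``offset_cluster`` adds a constant (scanner offset
    analog). Labels and landmarks are untouched by construction.
    """
    if mode == "invert_fluid":
        lo, hi = float(vol.data.min()), float(vol.data.max())
        data = (lo + hi) - vol.data
    elif mode == "offset_cluster":
        data = vol.data + offset
    else:
        raise ValidationError(f"unknown domain shift {mode!r}")
    return Volume(data=data, spacing=vol.spacing, origin=vol.origin)


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 32-voxel-cube phantom with proportionally shrunk geometry.

    Used by the scaled-down training studies and the test suite, where the
    full 64-cube default would be needlessly slow.
    """
    base = dict(
        shape=(32, 32, 32),
        turns=2.5,
        spiral_radius_start=5.5,
        spiral_radius_end=1.5,
        spiral_height=7.0,
        tube_radius=1.6,
        canal_radii=(3.2, 3.5, 3.8),
        canal_tube_radius=1.0,
        vestibule_radii=(2.2, 1.8, 1.8),
    )
    base.update(overrides)
    return PhantomSpec(**base)


SMALL_JITTER = {
    "turns": (2.2, 2.8),
    "spiral_radius_start": (5.0, 6.0),
    "tube_radius": (1.4, 1.8),
    "rotation": (-15.0, 15.0),
}


def small_cohort(n: int, seed: int = 0, **spec_overrides):
    """Cohort of 32-cube phantoms with jitter scaled to their geometry."""
    return generate_cohort(
        n, seed=seed, base_spec=small_phantom_spec(**spec_overrides),
        jitter=SMALL_JITTER,
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    jitter: dict | None = None,
):
    """Generate ``n`` phantoms with jittered geometry.

    ``jitter`` maps PhantomSpec field names to (low, high) uniform ranges;
    the default varies turns, spiral radius and tube radius by about +/-10%
    of the base spec and rotates by up to +/-15 degrees, emulating
    anatomical variability at any phantom scale. Per-instance seeds derive
    from the master seed.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    base = base_spec or PhantomSpec()
    ranges = {
        "turns": (0.88 * base.turns, 1.12 * base.turns),
        "spiral_radius_start": (0.91 * base.spiral_radius_start,
                                1.09 * base.spiral_radius_start),
        "tube_radius": (0.88 * base.tube_radius, 1.12 * base.tube_radius),
        "rotation": (-15.0, 15.0),
    }
    if jitter is not None:
        ranges.update(jitter)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    out = []
    for i in range(n):
        rng = np.random.default_rng(child_seeds[i])
        overrides = {}
        for name, (lo, hi) in ranges.items():
            if name == "rotation":
                overrides[name] = tuple(rng.uniform(lo, hi, size=3))
            else:
                overrides[name] = float(rng.uniform(lo, hi))
        overrides["seed"] = int(child_seeds[i])
        out.append(generate_phantom(replace(base, **overrides)))
    return out
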