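"""Core containers and I/O: volumes, binary labels, landmark sets.

Conventions
-----------
* Voxel coordinates are 0-based indices in array order ``(axis0, axis1,
  axis2)``; conversion to/from physical units happens only at I/O
  boundaries.
* ``spacing`` and ``origin`` are stored in micrometres. NIfTI headers carry
  millimetres, so reading/writing converts by a factor of 1000.
* Landmark files may be JSON or CSV (voxel units) or 3DSlicer fiducial FCSV
  (physical millimetres, converted using the paired grid's spacing/origin).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

LANDMARK_NAMES = ("helicotrema", "oval_window", "round_window")


class VolumeIOError(IOError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and physical origin (µm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume:
    """Binary foreground labels on a grid congruent with its paired Volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"label volume must be 3D, got {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"labels must be binary 0/1, found values {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LandmarkSet:
    """The three inner-ear landmarks, as 0-based voxel coordinate vectors."""

    helicotrema: np.ndarray
    oval_window: np.ndarray
    round_window: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValidationError(f"landmark {name} must be a 3-vector, got {v.shape}")
            setattr(self, name, v)

    def as_dict(self) -> dict[str, list[float]]:
        return {name: list(map(float, getattr(self, name))) for name in LANDMARK_NAMES}

    def as_array(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in LANDMARK_NAMES])

    def validate_bounds(self, shape):
        for name in LANDMARK_NAMES:
            c = getattr(self, name)
            if (c < 0).any() or (c > np.asarray(shape) - 1).any():
                raise ValidationError(
                    f"landmark {name} at {c} lies outside volume bounds {shape}"
                )


# -- volume I/O -----------------------------------------------------------


def _affine_from(spacing_um, origin_um) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(spacing_um) / 1000.0)
    aff[:3, 3] = np.asarray(origin_um) / 1000.0
    return aff


def write_volume(vol: Volume | LabelVolume, path) -> Path:
    """Write as NIfTI (.nii or .nii.gz); spacing/origin stored in mm."""
    path = Path(path)
    img = nib.Nifti1Image(np.asanyarray(vol.data), _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(np.asarray(vol.spacing) / 1000.0))
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> Volume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeIOError(f"missing or invalid spacing metadata in {path}")
    data = np.asanyarray(img.dataobj)
    origin = tuple(float(v) * 1000.0 for v in img.affine[:3, 3])
    return Volume(
        data=np.ascontiguousarray(data),
        spacing=tuple(float(z) * 1000.0 for z in zooms),
        origin=origin,
    )


def _read_dicom_series(path: Path) -> Volume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise VolumeIOError(f"no DICOM series found in directory {path}")
    reader.SetFileNames(names)
    img = reader.Execute()
    # SimpleITK arrays come back (z, y, x); spacing is (x, y, z) in mm
    data = sitk.GetArrayFromImage(img)
    sp = img.GetSpacing()[::-1]
    og = img.GetOrigin()[::-1]
    return Volume(
        data=np.ascontiguousarray(data),
        spacing=tuple(1000.0 * s for s in sp),
        origin=tuple(1000.0 * o for o in og),
    )


def read_volume(path) -> Volume:
    """Read a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    suffixes = "".join(path.suffixes[-2:])
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    raise VolumeIOError(
        f"unsupported volume format for {path}: expected .nii/.nii.gz or a DICOM directory"
    )


def read_label(path) -> LabelVolume:
    v = read_volume(path)
    return LabelVolume(data=v.data, spacing=v.spacing, origin=v.origin)


# -- landmark I/O ---------------------------------------------------------


def write_landmarks(lm: LandmarkSet, path) -> Path:
    """Write landmarks in voxel units as JSON (.json) or CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(lm.as_dict(), indent=2))
    elif path.suffix == ".csv":
        with path.open("w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["name", "i", "j", "k"])
            for name in LANDMARK_NAMES:
                wr.writerow([name, *map(float, getattr(lm, name))])
    else:
        raise VolumeIOError(f"unsupported landmark format {path.suffix}")
    return path


_ALIASES = {
    "helicotrema": "helicotrema",
    "oval": "oval_window",
    "oval_window": "oval_window",
    "round": "round_window",
    "round_window": "round_window",
}


def _finalize(points: dict[str, np.ndarray]) -> LandmarkSet:
    missing = [n for n in LANDMARK_NAMES if n not in points]
    if missing:
        raise ValidationError(f"missing landmark(s): {', '.join(missing)}")
    return LandmarkSet(**{n: points[n] for n in LANDMARK_NAMES})


def read_landmarks(path, spacing=None, origin=None) -> LandmarkSet:
    """Read landmarks; FCSV files require the paired grid's spacing (µm).

    JSON/CSV store voxel coordinates directly. FCSV (3DSlicer markups) stores
    physical millimetre coordinates, converted via
    ``voxel = (mm * 1000 - origin) / spacing`` per axis.
    """
    path = Path(path)
    points: dict[str, np.ndarray] = {}
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        for key, val in raw.items():
            name = _ALIASES.get(key.lower())
            if name:
                points[name] = np.asarray(val, dtype=float)
    elif path.suffix == ".csv":
        with path.open() as fh:
            for row in csv.DictReader(fh):
                name = _ALIASES.get(row["name"].lower())
                if name:
                    points[name] = np.array(
                        [float(row["i"]), float(row["j"]), float(row["k"])]
                    )
    elif path.suffix == ".fcsv":
        if spacing is None:
            raise ValidationError("reading FCSV needs the paired grid's spacing")
        spacing = np.asarray(spacing, dtype=float)
        origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            # Slicer fiducial rows: id,x,y,z,...,label,...
            label = parts[11] if len(parts) > 11 else parts[-1]
            name = _ALIASES.get(label.strip().lower())
            if name:
                mm = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
                points[name] = (mm * 1000.0 - origin) / spacing
    else:
        raise VolumeIOError(f"unsupported landmark format {path.suffix}")
    return _finalize(points)


def write_fcsv(lm: LandmarkSet, path, spacing, origin=(0.0, 0.0, 0.0)) -> Path:
    """Write landmarks as a 3DSlicer fiducial file (physical mm)."""
    path = Path(path)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for idx, name in enumerate(LANDMARK_NAMES, start=1):
        mm = (np.asarray(getattr(lm, name)) * spacing + origin) / 1000.0
        lines.append(
            f"{idx},{mm[0]:.6f},{mm[1]:.6f},{mm[2]:.6f},0,0,0,1,1,1,0,{name},,"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# -- resampling -----------------------------------------------------------


def resample_isotropic(
    vol: Volume | LabelVolume,
    target_um: float,
    landmarks: LandmarkSet | None = None,
):
    """Resample to an isotropic grid of edge ``target_um`` micrometres.

    Intensities are interpolated trilinearly, labels nearest-neighbor.
    Output shape per axis is ``round(shape * spacing / target)``. If a
    LandmarkSet is given, its coordinates are rescaled by
    ``spacing / target`` per axis and the pair is returned.
    """
    if target_um <= 0:
        raise ValidationError("target spacing must be positive")
    spacing = np.asarray(vol.spacing, dtype=float)
    factors = spacing / float(target_um)
    out_shape = np.round(np.asarray(vol.data.shape) * factors).astype(int)
    if (out_shape < 1).any():
        raise ValidationError(
            f"target spacing {target_um} µm degenerates the grid to {tuple(out_shape)}"
        )
    is_label = isinstance(vol, LabelVolume)
    if np.allclose(factors, 1.0):
        out_data = vol.data.copy()
    else:
        zoom = out_shape / np.asarray(vol.data.shape)
        out_data = ndimage.zoom(
            vol.data.astype(np.uint8 if is_label else np.float32),
            zoom,
            order=0 if is_label else 1,
            mode="nearest",
            grid_mode=False,
        )
        out_data = out_data[: out_shape[0], : out_shape[1], : out_shape[2]]
    cls = LabelVolume if is_label else Volume
    out = cls(data=out_data, spacing=(target_um,) * 3, origin=vol.origin)
    if landmarks is None:
        return out
    scaled = LandmarkSet(
        **{n: np.asarray(getattr(landmarks, n)) * factors for n in LANDMARK_NAMES}
    )
    return out, scaled
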