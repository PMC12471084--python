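"""Volume containers, NIfTI I/O, resampling, depth cropping, ROI masking.

Axis convention: arrays are indexed (depth, height, width); depth (axis 0)
is the pseudo-temporal slicing axis used by the recurrent refinement stage.
Landmark points are stored in the same (d, h, w) voxel-coordinate order; the
CSV interface exposes them as columns id,x,y,z with x=width, y=height,
z=depth (the conventional image-coordinate order).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Sequence, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality", "Volume", "LabelMask", "LandmarkSet",
    "read_volume", "write_volume", "read_mask", "write_mask",
    "resample_to_grid", "crop_depth", "pad_depth", "apply_roi",
    "read_landmarks", "write_landmarks", "read_field", "write_field",
]


class Modality(str, Enum):
    MRI_LIKE = "MRI_like"
    TRUS_LIKE = "TRUS_like"
    UNKNOWN = "unknown"


@dataclass
class Volume:
    """Dense 3D scalar grid with voxel spacing and a modality tag."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.UNKNOWN

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMask:
    """Binary mask on the same grid conventions as Volume."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LandmarkSet:
    """Corresponding points in voxel coordinates, (d, h, w) order."""

    points: np.ndarray
    ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.points))]
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points must have equal length")

    def __len__(self):
        return len(self.points)


# -- NIfTI I/O ------------------------------------------------------------


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def read_volume(path, modality: Modality = Modality.UNKNOWN) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # pragma: no cover - malformed file branch
        raise ValueError(f"malformed NIfTI file: {path}") from exc
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, modality)


def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing_mm))
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask((vol.data > 0.5).astype(np.uint8), vol.spacing_mm)


def write_mask(mask: LabelMask, path) -> None:
    write_volume(Volume(mask.data.astype(np.float32), mask.spacing_mm), path)


def read_field(path) -> np.ndarray:
    """Read a deformation field stored as 4D NIfTI (last axis = component)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected (D,H,W,3) field NIfTI, got {data.shape}")
    return np.moveaxis(data, -1, 0)


def write_field(phi: np.ndarray, spacing_mm, path) -> None:
    phi = np.asarray(phi, dtype=np.float32)
    if phi.ndim != 4 or phi.shape[0] != 3:
        raise ValueError(f"field must be (3,D,H,W), got {phi.shape}")
    img = nib.Nifti1Image(np.moveaxis(phi, 0, -1), _affine(spacing_mm))
    nib.save(img, str(path))


# -- grid operations ------------------------------------------------------


def resample_to_grid(vol: Volume, target_shape, is_label: bool = False) -> Volume:
    """Resample to a new grid, preserving physical extent.

    Trilinear for images, nearest-neighbor for label volumes.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if any(s < 2 for s in target_shape):
        raise ValueError(f"target shape must be >= 2 per axis, got {target_shape}")
    src_shape = vol.data.shape
    if target_shape == src_shape:
        return Volume(vol.data.copy(), vol.spacing_mm, vol.modality)
    factors = [t / s for t, s in zip(target_shape, src_shape)]
    out = ndimage.zoom(
        np.asarray(vol.data, dtype=np.float32),
        factors,
        order=0 if is_label else 1,
        mode="nearest",
        grid_mode=True,
    )
    # zoom with grid_mode can be off by one voxel in shape for odd factors
    out = out[: target_shape[0], : target_shape[1], : target_shape[2]]
    spacing = tuple(
        sp * s / t for sp, s, t in zip(vol.spacing_mm, src_shape, target_shape)
    )
    return Volume(out, spacing, vol.modality)


def crop_depth(vol: Volume, n_slices: int = 4) -> Volume:
    """Drop the first and last ``n_slices`` depth planes."""
    if n_slices < 0:
        raise ValueError("n_slices must be nonnegative")
    depth = vol.data.shape[0]
    if depth <= 2 * n_slices:
        raise ValueError(
            f"depth {depth} too small to crop {n_slices} planes from each end"
        )
    if n_slices == 0:
        return Volume(vol.data.copy(), vol.spacing_mm, vol.modality)
    return Volume(vol.data[n_slices:depth - n_slices], vol.spacing_mm, vol.modality)


def pad_depth(vol: Volume, n_slices: int = 4) -> Volume:
    """Zero-pad ``n_slices`` planes back onto both depth ends (inverse of crop)."""
    if n_slices == 0:
        return Volume(vol.data.copy(), vol.spacing_mm, vol.modality)
    pad = ((n_slices, n_slices), (0, 0), (0, 0))
    return Volume(np.pad(vol.data, pad), vol.spacing_mm, vol.modality)


def apply_roi(vol: Volume, mask: LabelMask) -> Volume:
    if vol.data.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch: volume {vol.data.shape} vs mask {mask.data.shape}"
        )
    return Volume(vol.data * mask.data, vol.spacing_mm, vol.modality)


# -- landmark CSV ---------------------------------------------------------


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "z"])
        for lid, (d, h, w) in zip(lms.ids, lms.points):
            writer.writerow([lid, repr(float(w)), repr(float(h)), repr(float(d))])


def read_landmarks(path) -> LandmarkSet:
    points, ids = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["id"])
            points.append((float(row["z"]), float(row["y"]), float(row["x"])))
    return LandmarkSet(np.asarray(points), ids)
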