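"""Synthetic cross-modal prostate phantoms with known ground-truth deformations.

Each case consists of a base ellipsoidal anatomy rendered under two intensity
models: a smooth high-contrast "MRI-like" moving volume and a speckled
"TRUS-like" fixed volume with radial intensity falloff. The ground truth is a
stationary velocity field integrated by the same scaling-and-squaring routine
used at registration time, so recovery experiments compare like with like.
The moving volume shows the anatomy warped by the *inverse* flow, hence
warping it by ``gt_field`` re-aligns it to the fixed volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .deform import sample_field_at_points, vecint, warp
from .volume_io import LabelMask, LandmarkSet, Modality, Volume

__all__ = ["PhantomSpec", "PhantomCase", "make_velocity_field", "make_phantom_pair",
           "make_4d_sequence"]


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    organ_semiaxes_vox: Tuple[float, float, float] = (9.0, 11.0, 10.0)
    deform_amplitude_vox: float = 3.0
    deform_smoothness_vox: float = 4.0
    speckle_sigma: float = 0.3
    noise_sigma: float = 0.03
    n_landmarks: int = 10
    seed: int = 0
    anatomy_seed: Optional[int] = None  # share organ texture across cases
    deform_seed: Optional[int] = None   # share the base deformation family

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid must be >= 8 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.deform_amplitude_vox < 0:
            raise ValueError("deform_amplitude_vox must be nonnegative")
        if self.deform_smoothness_vox <= 0:
            raise ValueError("deform_smoothness_vox must be positive")
        if self.speckle_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.n_landmarks < 1:
            raise ValueError("n_landmarks must be positive")
        for n, a in zip(self.grid_shape, self.organ_semiaxes_vox):
            if a <= 0:
                raise ValueError("organ semiaxes must be positive")
            if n / 2.0 - a < 2.0:
                raise ValueError(
                    f"organ (semiaxis {a}) does not fit grid axis of {n} voxels "
                    "with a 2-voxel margin"
                )


@dataclass
class PhantomCase:
    moving: Volume
    fixed: Volume
    moving_mask: LabelMask
    fixed_mask: LabelMask
    landmarks_moving: LandmarkSet
    landmarks_fixed: LandmarkSet
    gt_field: np.ndarray  # (3, D, H, W) voxel displacements
    case_id: str = "case"
    extras: dict = field(default_factory=dict)


def make_velocity_field(shape, amplitude: float, smoothness: float, seed: int) -> np.ndarray:
    """Random smooth stationary velocity field, (3, D, H, W).

    Gaussian-smoothed white noise, rescaled so the maximum displacement
    magnitude of the *integrated* field is approximately ``amplitude`` voxels.
    Deterministic in ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ValueError(f"shape must be >= 8 per axis, got {shape}")
    if smoothness <= 0:
        raise ValueError(f"smoothness must be positive, got {smoothness}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be nonnegative, got {amplitude}")
    if amplitude == 0:
        return np.zeros((3,) + shape, dtype=np.float64)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((3,) + shape)
    for i in range(3):
        v[i] = ndimage.gaussian_filter(v[i], sigma=smoothness, mode="reflect")
    mag = np.sqrt((v ** 2).sum(axis=0)).max()
    v *= amplitude / mag
    # one calibration pass: match the post-integration maximum displacement
    phi = vecint(v)
    peak = np.sqrt((phi ** 2).sum(axis=0)).max()
    if peak > 0:
        v *= amplitude / peak
    return v


def _tissue_maps(spec: PhantomSpec):
    """Organ mask, label map (bg=0, organ=1, nodule=2), and interior texture.

    The texture is a smooth seeded random field confined to the organ; both
    modalities render it (with different gains) so intensity-based
    similarity carries dense correspondence cues inside the gland, not just
    at its boundary.
    """
    shape = spec.grid_shape
    center = np.array([(s - 1) / 2.0 for s in shape])
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = sum(
        ((g - c) / a) ** 2
        for g, c, a in zip(grids, center, spec.organ_semiaxes_vox)
    )
    organ = r2 <= 1.0
    nod_center = center + np.array(spec.organ_semiaxes_vox) * np.array([0.25, -0.2, 0.15])
    nod_axes = np.array(spec.organ_semiaxes_vox) * 0.35
    rn2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, nod_center, nod_axes)
    )
    labels = np.zeros(shape, dtype=np.int8)
    labels[organ] = 1
    labels[(rn2 <= 1.0) & organ] = 2
    anatomy = spec.seed if spec.anatomy_seed is None else spec.anatomy_seed
    tex_rng = np.random.default_rng(anatomy + 7)
    texture = ndimage.gaussian_filter(
        tex_rng.standard_normal(shape), sigma=2.5, mode="reflect"
    )
    texture /= max(np.abs(texture).max(), 1e-9)
    texture *= organ
    return organ.astype(np.float64), labels, texture


def _render(labels: np.ndarray, levels, texture: np.ndarray, tex_gain: float,
            blur: float = 0.7) -> np.ndarray:
    img = np.choose(labels, levels).astype(np.float64) + tex_gain * texture
    return ndimage.gaussian_filter(img, sigma=blur, mode="nearest")


_MRI_LEVELS = (0.20, 0.80, 0.50)
_TRUS_LEVELS = (0.15, 0.45, 0.70)
_MRI_TEX_GAIN = 0.35
_TRUS_TEX_GAIN = -0.25  # inverted contrast relation across modalities


def _radial_falloff(shape) -> np.ndarray:
    center = np.array([(s - 1) / 2.0 for s in shape])
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = sum(((g - c) / (s / 2.0)) ** 2 for g, c, s in zip(grids, center, shape))
    return 1.0 / (1.0 + 0.6 * r2)


def _sample_landmarks(organ_mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    eroded = ndimage.binary_erosion(organ_mask > 0.5, iterations=2)
    cand = np.argwhere(eroded)
    if len(cand) < n:
        cand = np.argwhere(organ_mask > 0.5)
    idx = rng.choice(len(cand), size=n, replace=False)
    return cand[idx].astype(np.float64)


def make_phantom_pair(spec: PhantomSpec) -> PhantomCase:
    """Generate one pre-aligned cross-modal pair with ground-truth deformation."""
    rng = np.random.default_rng(spec.seed)
    organ, labels, texture = _tissue_maps(spec)
    clean_a = _render(labels, _MRI_LEVELS, texture, _MRI_TEX_GAIN)
    clean_b = _render(labels, _TRUS_LEVELS, texture, _TRUS_TEX_GAIN)

    v_seed = spec.seed + 1 if spec.deform_seed is None else spec.deform_seed
    v = make_velocity_field(
        spec.grid_shape, spec.deform_amplitude_vox, spec.deform_smoothness_vox,
        seed=v_seed,
    )
    gt = vecint(v)
    inv = vecint(-v)

    # moving = modality-A rendering of anatomy warped by the inverse flow,
    # so warp(moving, gt) re-aligns it to the fixed anatomy
    moving_geom = warp(clean_a, inv, mode="trilinear")
    moving_data = moving_geom + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    moving_mask = warp(organ, inv, mode="trilinear") > 0.5

    speckle = np.exp(rng.normal(0.0, spec.speckle_sigma, spec.grid_shape))
    fixed_data = clean_b * speckle * _radial_falloff(spec.grid_shape)
    fixed_data = fixed_data + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    fixed_mask = organ > 0.5

    lm_fixed = _sample_landmarks(organ, spec.n_landmarks, rng)
    lm_moving = lm_fixed + sample_field_at_points(gt, lm_fixed)
    ids = [f"lm{i}" for i in range(spec.n_landmarks)]

    sp = spec.spacing_mm
    return PhantomCase(
        moving=Volume(moving_data.astype(np.float32), sp, Modality.MRI_LIKE),
        fixed=Volume(fixed_data.astype(np.float32), sp, Modality.TRUS_LIKE),
        moving_mask=LabelMask(moving_mask.astype(np.uint8), sp),
        fixed_mask=LabelMask(fixed_mask.astype(np.uint8), sp),
        landmarks_moving=LandmarkSet(lm_moving, list(ids)),
        landmarks_fixed=LandmarkSet(lm_fixed, list(ids)),
        gt_field=gt.astype(np.float64),
        case_id=f"phantom_{spec.seed}",
        extras={"velocity": v},
    )


def make_4d_sequence(spec: PhantomSpec, n_frames: int, period: int) -> List[PhantomCase]:
    """Pseudo-respiratory sequence: frame t's ground truth is the base field's
    velocity scaled by sin(2*pi*t/period), sharing one anatomy."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if period <= 0:
        raise ValueError("period must be positive")
    frames = []
    for t in range(n_frames):
        scale = float(np.sin(2.0 * np.pi * t / period))
        if abs(scale) < 1e-9:  # exact identity at zero phase
            scale = 0.0
        frame_spec = replace(
            spec, deform_amplitude_vox=abs(scale) * spec.deform_amplitude_vox
        )
        case = _scaled_case(frame_spec, spec, scale, t)
        frames.append(case)
    return frames


def _scaled_case(frame_spec: PhantomSpec, base_spec: PhantomSpec, scale: float,
                 t: int) -> PhantomCase:
    rng = np.random.default_rng(base_spec.seed)
    organ, labels, texture = _tissue_maps(base_spec)
    clean_a = _render(labels, _MRI_LEVELS, texture, _MRI_TEX_GAIN)
    clean_b = _render(labels, _TRUS_LEVELS, texture, _TRUS_TEX_GAIN)
    v_base = make_velocity_field(
        base_spec.grid_shape, base_spec.deform_amplitude_vox,
        base_spec.deform_smoothness_vox, seed=base_spec.seed + 1,
    )
    v = scale * v_base
    gt = vecint(v)
    inv = vecint(-v)
    moving_geom = warp(clean_a, inv, mode="trilinear")
    moving_data = moving_geom + rng.normal(0.0, base_spec.noise_sigma, base_spec.grid_shape)
    moving_mask = warp(organ, inv, mode="trilinear") > 0.5
    speckle = np.exp(rng.normal(0.0, base_spec.speckle_sigma, base_spec.grid_shape))
    fixed_data = clean_b * speckle * _radial_falloff(base_spec.grid_shape)
    fixed_data = fixed_data + rng.normal(0.0, base_spec.noise_sigma, base_spec.grid_shape)
    lm_fixed = _sample_landmarks(organ, base_spec.n_landmarks, rng)
    lm_moving = lm_fixed + sample_field_at_points(gt, lm_fixed)
    ids = [f"lm{i}" for i in range(base_spec.n_landmarks)]
    sp = base_spec.spacing_mm
    return PhantomCase(
        moving=Volume(moving_data.astype(np.float32), sp, Modality.MRI_LIKE),
        fixed=Volume(fixed_data.astype(np.float32), sp, Modality.TRUS_LIKE),
        moving_mask=LabelMask(moving_mask.astype(np.uint8), sp),
        fixed_mask=LabelMask((organ > 0.5).astype(np.uint8), sp),
        landmarks_moving=LandmarkSet(lm_moving, list(ids)),
        landmarks_fixed=LandmarkSet(lm_fixed, list(ids)),
        gt_field=gt.astype(np.float64),
        case_id=f"phantom_{base_spec.seed}_t{t}",
        extras={"velocity": v, "scale": scale},
    )
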