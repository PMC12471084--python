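"""Diffeomorphic deformation operations.

Displacement convention: a field ``phi`` of shape (3, D, H, W) stores
voxel-unit displacements with channel order (d, h, w); warping samples the
source at ``p + phi(p)``. Sampling positions outside the grid clamp to the
border. All public functions accept either plain numpy arrays or autograd
``Tensor``s (batched as (N, C, D, H, W) / (N, 3, D, H, W)); the Tensor path
is fully differentiable w.r.t. both the image and the field.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, make_op

__all__ = ["warp", "compose", "vecint", "jacobian_stats"]


# -- numpy kernels --------------------------------------------------------


def _sample_coords(shape, phi):
    """Clamped sampling coordinates p + phi(p) for a (3,D,H,W) field."""
    grids = np.meshgrid(*[np.arange(s, dtype=phi.dtype) for s in shape], indexing="ij")
    coords = [g + phi[i] for i, g in enumerate(grids)]
    clamped = [np.clip(c, 0, s - 1) for c, s in zip(coords, shape)]
    inbound = [(c >= 0) & (c <= s - 1) for c, s in zip(coords, shape)]
    return clamped, inbound


def _warp_trilinear(img, phi):
    """img (C,D,H,W), phi (3,D,H,W) -> warped (C,D,H,W)."""
    C = img.shape[0]
    shape = img.shape[1:]
    (cd, ch, cw), _ = _sample_coords(shape, phi)
    f0 = [np.floor(c).astype(np.int64) for c in (cd, ch, cw)]
    f0 = [np.clip(f, 0, s - 1) for f, s in zip(f0, shape)]
    f1 = [np.clip(f + 1, 0, s - 1) for f, s in zip(f0, shape)]
    t = [c - f for c, f in zip((cd, ch, cw), f0)]
    flat = img.reshape(C, -1)
    H, W = shape[1], shape[2]
    out = np.zeros((C,) + shape, dtype=img.dtype)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                idx = ((f1[0] if a else f0[0]) * H + (f1[1] if b else f0[1])) * W + (
                    f1[2] if c else f0[2]
                )
                w = (
                    (t[0] if a else 1 - t[0])
                    * (t[1] if b else 1 - t[1])
                    * (t[2] if c else 1 - t[2])
                )
                out += flat[:, idx.ravel()].reshape((C,) + shape) * w
    return out


def _warp_nearest(img, phi):
    C = img.shape[0]
    shape = img.shape[1:]
    coords, _ = _sample_coords(shape, phi)
    idx = [np.rint(c).astype(np.int64) for c in coords]
    idx = [np.clip(i, 0, s - 1) for i, s in zip(idx, shape)]
    lin = (idx[0] * shape[1] + idx[1]) * shape[2] + idx[2]
    return img.reshape(C, -1)[:, lin.ravel()].reshape((C,) + shape)


def _warp_backward(img, phi, gy):
    """Gradients of trilinear warp w.r.t. img and phi (both (C/3,D,H,W))."""
    C = img.shape[0]
    shape = img.shape[1:]
    (cd, ch, cw), inbound = _sample_coords(shape, phi)
    f0 = [np.clip(np.floor(c).astype(np.int64), 0, s - 1) for c, s in zip((cd, ch, cw), shape)]
    f1 = [np.clip(f + 1, 0, s - 1) for f, s in zip(f0, shape)]
    t = [c - f for c, f in zip((cd, ch, cw), f0)]
    H, W = shape[1], shape[2]
    flat = img.reshape(C, -1)
    gimg = np.zeros_like(flat)
    gphi = np.zeros((3,) + shape, dtype=np.result_type(phi, np.float32))
    gyf = gy.reshape(C, -1)
    n_vox = flat.shape[1]
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                idx = (
                    ((f1[0] if a else f0[0]) * H + (f1[1] if b else f0[1])) * W
                    + (f1[2] if c else f0[2])
                ).ravel()
                wd = t[0] if a else 1 - t[0]
                wh = t[1] if b else 1 - t[1]
                ww = t[2] if c else 1 - t[2]
                sd = 1.0 if a else -1.0
                sh = 1.0 if b else -1.0
                sw = 1.0 if c else -1.0
                w = (wd * wh * ww).ravel()
                for ch in range(C):  # bincount scatter beats ufunc.at
                    gimg[ch] += np.bincount(
                        idx, weights=gyf[ch] * w, minlength=n_vox
                    ).astype(gimg.dtype, copy=False)
                vals = flat[:, idx].reshape((C,) + shape)
                prod = (gy * vals).sum(axis=0)
                gphi[0] += prod * sd * wh * ww
                gphi[1] += prod * wd * sh * ww
                gphi[2] += prod * wd * wh * sw
    for i in range(3):
        gphi[i] *= inbound[i]  # clamped coordinates have zero slope
    return gimg.reshape(img.shape), gphi


def warp(img, phi, mode: str = "trilinear"):
    """Warp an image/field by a displacement field.

    numpy path: img (D,H,W) or (C,D,H,W), phi (3,D,H,W).
    Tensor path: img (N,C,D,H,W), phi (N,3,D,H,W), differentiable.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode: {mode!r}")
    if isinstance(img, Tensor) or isinstance(phi, Tensor):
        return _warp_op(img, phi, mode)
    img = np.asarray(img)
    phi = np.asarray(phi, dtype=np.result_type(img.dtype, np.float32))
    squeeze = img.ndim == 3
    if squeeze:
        img = img[None]
    if img.shape[1:] != phi.shape[1:] or phi.shape[0] != 3:
        raise ValueError(f"shape mismatch: img {img.shape}, phi {phi.shape}")
    kern = _warp_trilinear if mode == "trilinear" else _warp_nearest
    if np.issubdtype(img.dtype, np.integer) or img.dtype == bool:
        work = img.astype(np.float64) if mode == "trilinear" else img
        out = kern(work, phi.astype(np.float64) if mode == "trilinear" else phi)
    else:
        out = kern(img, phi.astype(img.dtype))
    return out[0] if squeeze else out


def _warp_op(img, phi, mode):
    img = img if isinstance(img, Tensor) else Tensor(img)
    phi = phi if isinstance(phi, Tensor) else Tensor(phi)
    if img.ndim != 5 or phi.ndim != 5 or phi.shape[1] != 3:
        raise ValueError("Tensor warp expects img (N,C,D,H,W) and phi (N,3,D,H,W)")
    if img.shape[2:] != phi.shape[2:] or img.shape[0] != phi.shape[0]:
        raise ValueError(f"shape mismatch: img {img.shape}, phi {phi.shape}")
    N = img.shape[0]
    kern = _warp_trilinear if mode == "trilinear" else _warp_nearest
    y = np.stack([kern(img.data[n], phi.data[n]) for n in range(N)])

    def backward(gy):
        if mode == "nearest":
            raise NotImplementedError("nearest warp has no gradient")
        gi = np.empty_like(img.data)
        gp = np.empty_like(phi.data)
        for n in range(N):
            gi[n], gp[n] = _warp_backward(img.data[n], phi.data[n], gy[n])
        return gi, gp

    return make_op(y, (img, phi), backward)


def compose(phi_outer, phi_inner):
    """Composition (phi_outer o phi_inner)(p) = phi_inner(p) + phi_outer(p + phi_inner(p))."""
    if isinstance(phi_outer, Tensor) or isinstance(phi_inner, Tensor):
        return phi_inner + _warp_op(phi_outer, phi_inner, "trilinear")
    phi_outer = np.asarray(phi_outer)
    phi_inner = np.asarray(phi_inner)
    if phi_outer.shape != phi_inner.shape:
        raise ValueError(
            f"shape mismatch: {phi_outer.shape} vs {phi_inner.shape}"
        )
    return phi_inner + warp(phi_outer, phi_inner, mode="trilinear")


def vecint(v, steps: int = 7):
    """Integrate a stationary velocity field by scaling and squaring.

    phi_0 = v / 2**steps, then ``steps`` self-compositions; approximates the
    time-1 flow of the velocity field.
    """
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    if isinstance(v, Tensor):
        phi = v * float(2.0 ** -steps)
    else:
        v = np.asarray(v)
        if v.ndim != 4 or v.shape[0] != 3:
            raise ValueError(f"velocity field must be (3,D,H,W), got {v.shape}")
        phi = v * (2.0 ** -steps)
    for _ in range(steps):
        phi = compose(phi, phi)
    return phi


def jacobian_stats(phi):
    """Central-difference Jacobian determinant of p -> p + phi(p).

    Returns ``{"det_field": (D,H,W) array, "folding_fraction": float}``; the
    folding fraction counts interior voxels (one-voxel margin excluded) with
    non-positive determinant.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if phi.ndim != 4 or phi.shape[0] != 3:
        raise ValueError(f"field must be (3,D,H,W), got {phi.shape}")
    J = np.empty((3, 3) + phi.shape[1:], dtype=np.float64)
    for i in range(3):
        grads = np.gradient(phi[i], axis=(0, 1, 2))
        for j in range(3):
            J[i, j] = grads[j] + (1.0 if i == j else 0.0)
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    interior = det[1:-1, 1:-1, 1:-1]
    folding = float((interior <= 0).mean()) if interior.size else 0.0
    return {"det_field": det, "folding_fraction": folding}


def sample_field_at_points(phi: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample a (3,D,H,W) field at (M,3) voxel coordinates."""
    phi = np.asarray(phi, dtype=np.float64)
    pts = np.asarray(points, dtype=np.float64)
    shape = phi.shape[1:]
    out = np.zeros_like(pts)
    f0 = np.clip(np.floor(pts).astype(np.int64), 0, np.array(shape) - 1)
    f1 = np.clip(f0 + 1, 0, np.array(shape) - 1)
    t = pts - f0
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                idx = (
                    (f1[:, 0] if a else f0[:, 0]),
                    (f1[:, 1] if b else f0[:, 1]),
                    (f1[:, 2] if c else f0[:, 2]),
                )
                w = (
                    (t[:, 0] if a else 1 - t[:, 0])
                    * (t[:, 1] if b else 1 - t[:, 1])
                    * (t[:, 2] if c else 1 - t[:, 2])
                )
                out += phi[:, idx[0], idx[1], idx[2]].T * w[:, None]
    return out
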