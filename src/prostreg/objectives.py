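"""Composite training objective: gradient smoothness, soft Dice, and masked
negative mutual information.

``total = alpha * L_grad + beta * L_dice + gamma * L_mi`` with defaults
alpha=0.4, beta=1.0, gamma=1.0. Mutual information is estimated inside a
region of interest with a differentiable Parzen-window joint histogram and
reported in bits; since higher dependency should lower the loss, ``mi_loss``
returns the negative estimate.

All loss functions accept numpy arrays or autograd tensors and return a
scalar of the same kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor

__all__ = ["LossWeights", "dice_loss", "mi_loss", "grad_loss", "total_loss"]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.4   # gradient smoothness
    beta: float = 1.0    # Dice
    gamma: float = 1.0   # mutual information

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be nonnegative")


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def dice_loss(pred_mask, true_mask, eps: float = 1e-6,
              empty_is_zero: bool = False):
    """Soft Dice loss: 1 - 2*sum(p*t) / (sum(p) + sum(t) + eps).

    Masks may be real-valued in [0, 1] so warped labels stay differentiable.
    With ``empty_is_zero`` two empty masks give loss 0 (used for per-slab
    losses where a slab may not intersect the organ).
    """
    if _is_tensor(pred_mask, true_mask):
        p, t = as_tensor(pred_mask), as_tensor(true_mask)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
        if empty_is_zero and p.data.sum() + t.data.sum() < eps:
            return Tensor(np.float32(0.0))
        inter = (p * t).sum()
        return 1.0 - (2.0 * inter) / (p.sum() + t.sum() + eps)
    p = np.asarray(pred_mask, dtype=np.float64)
    t = np.asarray(true_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = p.sum() + t.sum()
    if empty_is_zero and denom < eps:
        return 0.0
    return float(1.0 - 2.0 * (p * t).sum() / (denom + eps))


def _parzen_weights(x, centers, sigma):
    # x: (M,) tensor; centers: (bins,) ndarray -> (M, bins), rows sum to 1
    x2 = x.reshape(-1, 1)
    z = (x2 - Tensor(centers[None, :])) * (1.0 / sigma)
    w = (z * z * -0.5).exp()
    return w / (w.sum(axis=1, keepdims=True) + 1e-12)


def mi_loss(a, b, roi, bins: int = 32, range_a=None, range_b=None):
    """Negative mutual information (bits) of two images inside a ROI.

    Differentiable Parzen-window estimate: Gaussian kernels of width equal
    to the bin width, ``bins`` bins spanning each image's observed range in
    the ROI (or explicit ``range_a``/``range_b`` (lo, hi) pairs, e.g. to keep
    per-slab histograms on a shared intensity scale).
    """
    tensor_mode = _is_tensor(a, b)
    a, b = as_tensor(a), as_tensor(b)
    roi_data = roi.data if hasattr(roi, "data") and not isinstance(roi, Tensor) else roi
    roi_arr = np.asarray(roi_data.data if isinstance(roi_data, Tensor) else roi_data)
    roi_idx = np.flatnonzero(roi_arr.reshape(-1) > 0.5)
    if roi_idx.size == 0:
        raise ValueError("mi_loss requires a nonempty ROI")
    av = a.reshape(-1)[roi_idx]
    bv = b.reshape(-1)[roi_idx]

    def centers_sigma(vals, rng_pair):
        if rng_pair is not None:
            lo, hi = float(rng_pair[0]), float(rng_pair[1])
        else:
            lo, hi = float(vals.min()), float(vals.max())
        if hi - lo < 1e-8:
            hi = lo + 1e-8
        edges = np.linspace(lo, hi, bins + 1)
        c = 0.5 * (edges[:-1] + edges[1:])
        return c.astype(np.float64), float(edges[1] - edges[0])

    ca, sa = centers_sigma(av.data, range_a)
    cb, sb = centers_sigma(bv.data, range_b)
    wa = _parzen_weights(av, ca, sa)
    wb = _parzen_weights(bv, cb, sb)
    n = float(roi_idx.size)
    pab = (wa.transpose((1, 0)) @ wb) * (1.0 / n)      # (bins, bins)
    pa = wa.mean(axis=0).reshape(-1, 1)
    pb = wb.mean(axis=0).reshape(1, -1)
    eps = 1e-12
    ratio = (pab + eps) / (pa * pb + eps)  # (bins,1)*(1,bins) broadcasts
    mi_bits = (pab * ratio.log()).sum() * (1.0 / _LN2)
    loss = -mi_bits
    return loss if tensor_mode else float(loss.data)


def grad_loss(phi):
    """Mean squared forward-difference gradient of a displacement field.

    Accepts (3,D,H,W) or batched (N,3,D,H,W); normalization is by the number
    of voxels |Omega| (and batch), summing over components and directions.
    """
    tensor_mode = _is_tensor(phi)
    phi = as_tensor(phi)
    if phi.ndim == 4:
        phi = phi.reshape((1,) + tuple(phi.shape))
    n_vox = float(np.prod(phi.shape[0:1] + phi.shape[2:]))
    total = None
    for ax in (2, 3, 4):
        sl_hi = [slice(None)] * 5
        sl_lo = [slice(None)] * 5
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d = phi[tuple(sl_hi)] - phi[tuple(sl_lo)]
        term = (d * d).sum()
        total = term if total is None else total + term
    out = total * (1.0 / n_vox)
    return out if tensor_mode else float(out.data)


def total_loss(grad_term, dice_term, mi_term, weights: LossWeights = LossWeights()):
    """alpha * L_grad + beta * L_dice + gamma * L_mi."""
    out = (
        weights.alpha * as_tensor(grad_term)
        + weights.beta * as_tensor(dice_term)
        + weights.gamma * as_tensor(mi_term)
    )
    if _is_tensor(grad_term, dice_term, mi_term):
        return out
    return float(out.data)
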