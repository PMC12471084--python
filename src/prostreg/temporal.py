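"""Pseudo-temporal refinement of static deformation fields.

The depth axis of a (3, D, H, W) field is treated as time: the field is cut
into T equal-depth slices, each slice is flattened and run through a
two-layer LSTM, hidden states are mapped back to slice shape by a fully
connected layer, and the refined slices are reassembled. Depth planes left
over by integer division pass through unchanged from the static field. A
two-branch subnet produces a per-slice task mask that balances registration
accuracy against deformation smoothness in the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._autograd import Tensor, as_tensor, concat, stack
from .nn import Linear, LSTM, Module

__all__ = ["SliceSequence", "TaskMask", "slice_flow", "concat_slices",
           "LstmRefiner", "TaskMaskNet", "masked_loss"]


@dataclass
class SliceSequence:
    """T equal-depth field slices plus the residual depth planes."""

    slices: List  # each (..., 3, d, H, W)
    residual: Optional[object]  # (..., 3, r, H, W) or None
    depth_axis: int

    @property
    def n_slices(self):
        return len(self.slices)

    @property
    def slice_depth(self):
        return self.slices[0].shape[self.depth_axis]


@dataclass
class TaskMask:
    """Per-case, per-slice two-task weights; rows sum to 1."""

    m: np.ndarray  # (N, T, 2)

    def __post_init__(self):
        arr = self.m.data if isinstance(self.m, Tensor) else np.asarray(self.m)
        if arr.ndim != 3 or arr.shape[-1] != 2:
            raise ValueError(f"task mask must be (N,T,2), got {arr.shape}")
        if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("task-mask rows must sum to 1")


def slice_flow(phi, n_slices: int = 10) -> SliceSequence:
    """Split a field along depth into ``n_slices`` equal slices.

    Accepts (3, D, H, W) arrays or batched (N, 3, D, H, W) tensors; the first
    ``T * floor(D/T)`` planes are split evenly, the rest become the residual.
    """
    is_tensor = isinstance(phi, Tensor)
    if not is_tensor:
        phi = np.asarray(phi)
    nd = phi.ndim
    if nd not in (4, 5):
        raise ValueError(f"field must be (3,D,H,W) or (N,3,D,H,W), got ndim={nd}")
    axis = nd - 3
    depth = phi.shape[axis]
    if depth < n_slices:
        raise ValueError(f"depth {depth} smaller than slice count {n_slices}")
    d = depth // n_slices
    slices = []
    for t in range(n_slices):
        sl = [slice(None)] * nd
        sl[axis] = slice(t * d, (t + 1) * d)
        slices.append(phi[tuple(sl)])
    residual = None
    if depth % n_slices:
        sl = [slice(None)] * nd
        sl[axis] = slice(n_slices * d, depth)
        residual = phi[tuple(sl)]
    return SliceSequence(slices=slices, residual=residual, depth_axis=axis)


def concat_slices(seq: SliceSequence):
    """Reassemble a SliceSequence into the full field (exact round trip)."""
    parts = list(seq.slices)
    if seq.residual is not None:
        parts.append(seq.residual)
    if isinstance(parts[0], Tensor):
        return concat(parts, axis=seq.depth_axis)
    return np.concatenate(parts, axis=seq.depth_axis)


class LstmRefiner(Module):
    """LSTM refinement of depth-sliced deformation fields.

    Each (3, d, H, W) slice is flattened, optionally down-projected, run
    through the LSTM, and mapped back to slice shape by a fully connected
    layer. ``residual=True`` adds the LSTM output to the static slices (an
    untrained refiner then perturbs the field only slightly);
    ``residual=False`` replaces them. Residual depth planes always pass
    through unchanged.
    """

    def __init__(self, field_shape, rng: np.random.Generator, n_slices: int = 10,
                 hidden: int = 128, layers: int = 2, residual: bool = True,
                 proj_dim: Optional[int] = None, out_scale: float = 1e-3):
        super().__init__()
        D, H, W = field_shape
        if D < n_slices:
            raise ValueError(f"depth {D} smaller than slice count {n_slices}")
        self.n_slices = n_slices
        self.slice_depth = D // n_slices
        self.slice_dim = 3 * self.slice_depth * H * W
        self.residual = residual
        self.field_shape = (int(D), int(H), int(W))
        d_in = self.slice_dim
        self.proj = None
        if proj_dim is not None:
            self.proj = Linear(self.slice_dim, proj_dim, rng)
            d_in = proj_dim
        self.lstm = LSTM(d_in, hidden, layers, rng)
        # small output init keeps the untrained refiner near the identity
        self.head = Linear(hidden, self.slice_dim, rng, init_std=out_scale)

    def forward(self, phi: Tensor) -> Tensor:
        phi = as_tensor(phi)
        if phi.ndim != 5:
            raise ValueError("refiner expects a batched (N,3,D,H,W) field")
        n = phi.shape[0]
        d, hh, ww = self.field_shape
        if tuple(phi.shape[2:]) != self.field_shape:
            raise ValueError(
                f"field shape {tuple(phi.shape[2:])} does not match refiner "
                f"configuration {self.field_shape}"
            )
        seq = slice_flow(phi, self.n_slices)
        xs = [s.reshape(n, self.slice_dim) for s in seq.slices]
        if self.proj is not None:
            xs = [self.proj(x) for x in xs]
        hs = self.lstm(xs)
        refined = []
        for t, h in enumerate(hs):
            y = self.head(h).reshape(n, 3, self.slice_depth, hh, ww)
            refined.append(seq.slices[t] + y if self.residual else y)
        parts = refined + ([seq.residual] if seq.residual is not None else [])
        return concat(parts, axis=2)


class TaskMaskNet(Module):
    """Two-branch subnet producing the per-slice task mask.

    Decoder feature maps are average-pooled per depth slab, each branch maps
    the pooled vector through two fully connected layers (hidden width 256)
    to a per-slice score, and the two scores are softmax-normalized.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 n_slices: int = 10, hidden: int = 256):
        super().__init__()
        self.n_slices = n_slices
        self.fc1_reg = Linear(channels, hidden, rng)
        self.fc2_reg = Linear(hidden, 1, rng)
        self.fc1_smooth = Linear(channels, hidden, rng)
        self.fc2_smooth = Linear(hidden, 1, rng)

    def forward(self, features: Tensor) -> Tensor:
        """features (N, C, D, H, W) -> mask tensor (N, T, 2), rows sum to 1."""
        features = as_tensor(features)
        n = features.shape[0]
        depth = features.shape[2]
        if depth < self.n_slices:
            raise ValueError(f"feature depth {depth} < slice count {self.n_slices}")
        d = depth // self.n_slices
        rows = []
        for t in range(self.n_slices):
            slab = features[:, :, t * d:(t + 1) * d]
            pooled = slab.mean(axis=(2, 3, 4))  # (N, C)
            w1 = self.fc2_reg(self.fc1_reg(pooled).relu())      # (N, 1)
            w2 = self.fc2_smooth(self.fc1_smooth(pooled).relu())
            rows.append(concat([w1, w2], axis=1))  # (N, 2)
        scores = stack(rows, axis=1)  # (N, T, 2)
        return scores.softmax(axis=2)


def masked_loss(mask, reg_slices: Sequence, smooth_slices: Sequence):
    """Mean over cases and slices of M[:,t,0]*L_reg[t] + M[:,t,1]*L_smooth[t]."""
    m = mask.m if isinstance(mask, TaskMask) else mask
    m = as_tensor(m)
    n, t_slices = m.shape[0], m.shape[1]
    if len(reg_slices) != t_slices or len(smooth_slices) != t_slices:
        raise ValueError(
            f"per-slice loss lists must have length {t_slices}, got "
            f"{len(reg_slices)} and {len(smooth_slices)}"
        )
    total = None
    for t in range(t_slices):
        term = (
            m[:, t, 0] * as_tensor(reg_slices[t])
            + m[:, t, 1] * as_tensor(smooth_slices[t])
        ).sum()
        total = term if total is None else total + term
    return total * (1.0 / float(n * t_slices))
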