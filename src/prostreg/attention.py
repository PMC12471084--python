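"""Cross-modal attention blocks for the dual-encoder registration network.

Three stages per encoder level: multi-scale feature aggregation (parallel
3/5/7 convolutions softmax-weighted by global pooled scores), dynamic
channel attention (sigmoid of a channel-axis 1D convolution over globally
pooled features), and a voxel-wise cross-modal sigmoid gate built from
channel-space projections. A 1x1x1 fusion convolution merges the two
enhanced streams for skip connections and the bottleneck.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, as_tensor, concat, stack
from .nn import Conv3d, Module, Parameter, conv3d, leaky_relu

__all__ = [
    "MultiScaleAggregation", "DynamicChannelAttention", "CrossModalGate",
    "CrossModalAttention", "FuseConv",
]

_SLOPE = 0.2


class MultiScaleAggregation(Module):
    """Parallel odd-kernel convolutions fused by softmax-normalized scores.

    Per scale k the scalar score is GAP + GMP pooled over all channels and
    voxels; scores are normalized across scales per batch item.
    """

    def __init__(self, channels: int, rng: np.random.Generator, kernels=(3, 5, 7)):
        super().__init__()
        self.kernels = tuple(kernels)
        self.convs = [Conv3d(channels, channels, k, rng) for k in self.kernels]

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite input to multi-scale aggregation")
        feats = [conv(x) for conv in self.convs]
        scores = stack(
            [f.mean(axis=(1, 2, 3, 4)) + f.max(axis=(1, 2, 3, 4)) for f in feats],
            axis=1,
        )  # (N, n_scales)
        weights = scores.softmax(axis=1)
        out = None
        for k, f in enumerate(feats):
            w = weights[:, k].reshape(-1, 1, 1, 1, 1)
            out = f * w if out is None else out + f * w
        return out

    def scale_weights(self, x: Tensor) -> np.ndarray:
        """Softmax scale weights only (diagnostic), shape (N, n_scales)."""
        x = as_tensor(x)
        feats = [conv(x) for conv in self.convs]
        scores = stack(
            [f.mean(axis=(1, 2, 3, 4)) + f.max(axis=(1, 2, 3, 4)) for f in feats],
            axis=1,
        )
        return scores.softmax(axis=1).data


class DynamicChannelAttention(Module):
    """Channel reweighting: sigmoid(Conv1D(GAP_spatial(F))) applied per channel.

    The 1D convolution runs along the channel axis with an odd kernel
    (default 3), no channel reduction.
    """

    def __init__(self, channels: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("channel-attention kernel size must be odd")
        self.kernel = kernel
        self.weight = Parameter(rng.normal(0, np.sqrt(1.0 / kernel), (kernel,)))
        self.bias = Parameter(np.zeros(1))

    def channel_weights(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        pooled = x.mean(axis=(2, 3, 4))  # (N, C)
        n, c = pooled.shape
        pad = self.kernel // 2
        zeros = Tensor(np.zeros((n, pad), dtype=np.float32))
        padded = concat([zeros, pooled, zeros], axis=1)
        acc = None
        for j in range(self.kernel):
            term = padded[:, j:j + c] * self.weight[j]
            acc = term if acc is None else acc + term
        return (acc + self.bias).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        w = self.channel_weights(x)
        return as_tensor(x) * w.reshape(w.shape[0], w.shape[1], 1, 1, 1)


class CrossModalGate(Module):
    """Voxel-wise single-channel attention map gating the second stream.

    att = sigmoid(W3^T relu(W1^T F1 + W2^T F2 + b12) + b3) with the channel
    projections applied independently at every voxel (1x1x1 maps).
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 2:
            raise ValueError(f"gate requires an even channel count, got {channels}")
        half = channels // 2
        self.w1 = Parameter(rng.normal(0, np.sqrt(2.0 / channels), (channels, half)))
        self.w2 = Parameter(rng.normal(0, np.sqrt(2.0 / channels), (channels, half)))
        self.w3 = Parameter(rng.normal(0, np.sqrt(2.0 / half), (half, 1)))
        self.b12 = Parameter(np.zeros(half))
        self.b3 = Parameter(np.zeros(1))

    def attention_map(self, f1: Tensor, f2: Tensor) -> Tensor:
        f1, f2 = as_tensor(f1), as_tensor(f2)
        if f1.shape != f2.shape:
            raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
        n, c = f1.shape[:2]
        spatial = f1.shape[2:]
        m = int(np.prod(spatial))
        a = f1.reshape(n, c, m).transpose((0, 2, 1))  # (N, M, C)
        b = f2.reshape(n, c, m).transpose((0, 2, 1))
        hidden = (a @ self.w1 + b @ self.w2 + self.b12).relu()
        att = (hidden @ self.w3 + self.b3).sigmoid()  # (N, M, 1)
        return att.transpose((0, 2, 1)).reshape((n, 1) + spatial)

    def forward(self, f1: Tensor, f2: Tensor):
        att = self.attention_map(f1, f2)
        return att, att * as_tensor(f2)


class CrossModalAttention(Module):
    """Full enhancement of a feature pair.

    Each stream runs through multi-scale aggregation and channel attention
    (both optional so the original single-scale gate is recoverable), then a
    cross-modal gate is applied. ``gate_mode='symmetric'`` gates both streams
    with two independent gates; ``'f2_only'`` gates only the second stream.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 gate_mode: str = "symmetric", enable_msfa: bool = True,
                 enable_dca: bool = True):
        super().__init__()
        if gate_mode not in ("symmetric", "f2_only"):
            raise ValueError(f"unknown gate_mode: {gate_mode!r}")
        self.gate_mode = gate_mode
        self.enable_msfa = enable_msfa
        self.enable_dca = enable_dca
        if enable_msfa:
            self.msfa_1 = MultiScaleAggregation(channels, rng)
            self.msfa_2 = MultiScaleAggregation(channels, rng)
        if enable_dca:
            self.dca_1 = DynamicChannelAttention(channels, rng)
            self.dca_2 = DynamicChannelAttention(channels, rng)
        self.gate_21 = CrossModalGate(channels, rng)
        if gate_mode == "symmetric":
            self.gate_12 = CrossModalGate(channels, rng)

    def forward(self, f1: Tensor, f2: Tensor):
        f1, f2 = as_tensor(f1), as_tensor(f2)
        if f1.shape != f2.shape:
            raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
        e1, e2 = f1, f2
        if self.enable_msfa:
            e1, e2 = self.msfa_1(e1), self.msfa_2(e2)
        if self.enable_dca:
            e1, e2 = self.dca_1(e1), self.dca_2(e2)
        _, gated2 = self.gate_21(e1, e2)
        if self.gate_mode == "symmetric":
            _, gated1 = self.gate_12(e2, e1)
        else:
            gated1 = e1
        return gated1, gated2


class FuseConv(Module):
    """Channel concatenation, 1x1x1 convolution, LeakyReLU(0.2)."""

    def __init__(self, c_in_total: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv3d(c_in_total, c_out, 1, rng)

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        a, b = as_tensor(a), as_tensor(b)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        return leaky_relu(self.conv(concat([a, b], axis=1)), _SLOPE)
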