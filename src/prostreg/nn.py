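"""Network building blocks on top of the autograd engine.

Convolutions use FFT-based correlation so that the 5x5x5 and 7x7x7 kernels
of the multi-scale attention cost the same as 3x3x3 at a given resolution.
All layers operate on (N, C, D, H, W) float32 arrays.
"""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np
from scipy import fft as sfft

from ._autograd import Tensor, as_tensor, make_op

__all__ = [
    "Module", "Parameter", "Conv3d", "Linear", "LSTM", "max_pool3d",
    "upsample_trilinear_2x", "Adam", "leaky_relu",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny torch-like module: tracks parameters and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Dict[str, Parameter]:
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p
        for k, m in self._modules.items():
            out.update(m.named_parameters(prefix + k + "."))
        return out

    def parameters(self) -> List[Parameter]:
        return list(self.named_parameters().values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    return x.leaky_relu(slope)


# -- convolution ----------------------------------------------------------


def _fft_corr_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' cross-correlation of x (N,Ci,D,H,W) with w (Co,Ci,k,k,k)."""
    D, H, W = x.shape[2:]
    kd, kh, kw = w.shape[2:]
    fshape = tuple(sfft.next_fast_len(s + k - 1) for s, k in zip((D, H, W), (kd, kh, kw)))
    fx = sfft.rfftn(x, fshape, axes=(2, 3, 4))
    fw = sfft.rfftn(np.flip(w, (2, 3, 4)), fshape, axes=(2, 3, 4))
    fy = np.einsum("niabc,oiabc->noabc", fx, fw)
    y = sfft.irfftn(fy, fshape, axes=(2, 3, 4))
    pd, ph, pw = (kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2
    return np.ascontiguousarray(
        y[:, :, pd:pd + D, ph:ph + H, pw:pw + W], dtype=x.dtype
    )


def _fft_corr_weight_grad(x: np.ndarray, gy: np.ndarray, ksize) -> np.ndarray:
    """Gradient w.r.t. the kernel of a 'same' cross-correlation.

    dw[o,i,j] = sum_{n,p} gy[n,o,p] * x[n,i,p + j - pad] for j in [0,k).
    Only lags |l| <= pad are needed, so padding to D + k - 1 avoids circular
    aliasing in the cropped window. Output channels are processed in chunks
    to bound the (o, i, freq) intermediate.
    """
    D, H, W = x.shape[2:]
    kd, kh, kw = ksize
    fshape = tuple(sfft.next_fast_len(s + k - 1) for s, k in zip((D, H, W), (kd, kh, kw)))
    fx = sfft.rfftn(x, fshape, axes=(2, 3, 4))
    fg = sfft.rfftn(np.flip(gy, (2, 3, 4)), fshape, axes=(2, 3, 4))
    pd, ph, pw = (kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2
    co, ci = gy.shape[1], x.shape[1]
    out = np.empty((co, ci, kd, kh, kw), dtype=x.dtype)
    chunk = max(1, int(2**24 // (ci * fx.shape[2] * fx.shape[3] * fx.shape[4] + 1)))
    for o0 in range(0, co, chunk):
        fz = np.einsum("niabc,noabc->oiabc", fx, fg[:, o0:o0 + chunk])
        z = sfft.irfftn(fz, fshape, axes=(2, 3, 4))
        lo_d, lo_h, lo_w = (D - 1 - pd) % fshape[0], (H - 1 - ph) % fshape[1], (W - 1 - pw) % fshape[2]
        out[o0:o0 + chunk] = z[:, :, lo_d:lo_d + kd, lo_h:lo_h + kh, lo_w:lo_w + kw]
    return out


def _offset_slices(shape, offsets):
    """Matched (out, in) slice tuples for a lag vector; zero padding implied."""
    out_sl, in_sl = [], []
    for s, l in zip(shape, offsets):
        a_lo = max(0, -l)
        a_hi = max(a_lo, min(s, s - l))  # empty when |lag| >= dim
        out_sl.append(slice(a_lo, a_hi))
        in_sl.append(slice(a_lo + l, a_hi + l))
    return tuple(out_sl), tuple(in_sl)


def _col_w(x: np.ndarray, kw: int) -> np.ndarray:
    """Stack the kw W-axis shifts of x: (N,C,D,H,W) -> (N, C*kw, D*H*W).

    Entry [n, i*kw + jw, p] equals x[n, i] at p shifted by jw - pad along W
    (zero outside). The W axis is contiguous, so the copies are cheap.
    """
    N, C, D, H, W = x.shape
    if kw == 1:
        return np.ascontiguousarray(x).reshape(N, C, -1)
    pw = (kw - 1) // 2
    xp = np.zeros((N, C, D, H, W + kw - 1), dtype=x.dtype)
    xp[..., pw:pw + W] = x
    cols = np.stack([xp[..., jw:jw + W] for jw in range(kw)], axis=2)
    return cols.reshape(N, C * kw, D * H * W)


def _gemm_corr_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same cross-correlation via per-(jd,jh) GEMMs on a W-unrolled buffer.

    The W kernel axis is folded into the GEMM contraction; the remaining
    (jd, jh) taps each need one GEMM and one shifted accumulation.
    """
    N, Ci, D, H, W = x.shape
    Co = w.shape[0]
    kd, kh, kw = w.shape[2:]
    pd, ph = (kd - 1) // 2, (kh - 1) // 2
    xcol = _col_w(x, kw)  # (N, Ci*kw, V)
    wrow = np.ascontiguousarray(w.transpose(2, 3, 0, 1, 4)).reshape(
        kd, kh * Co, Ci * kw
    )
    y = np.zeros((N, Co, D, H, W), dtype=x.dtype)
    nc = (slice(None), slice(None))
    for jd in range(kd):
        prod = np.matmul(wrow[jd][None], xcol).reshape(N, kh, Co, D, H, W)
        for jh in range(kh):
            out_sl, in_sl = _offset_slices((D, H), (jd - pd, jh - ph))
            y[nc + out_sl] += prod[:, jh][nc + in_sl]
    return y


def _gemm_corr_weight_grad(x: np.ndarray, gy: np.ndarray, ksize) -> np.ndarray:
    N, Ci, D, H, W = x.shape
    Co = gy.shape[1]
    kd, kh, kw = ksize
    xcol_t = _col_w(x, kw).transpose(0, 2, 1)  # (N, V, Ci*kw)
    gp = np.zeros((N, Co, D + kd - 1, H + kh - 1, W), dtype=gy.dtype)
    pd, ph = (kd - 1) // 2, (kh - 1) // 2
    gp[:, :, pd:pd + D, ph:ph + H] = gy
    dw = np.empty((kd, kh, Co, Ci * kw), dtype=x.dtype)
    for jd in range(kd):
        gys = np.stack([
            np.ascontiguousarray(
                gp[:, :, kd - 1 - jd:kd - 1 - jd + D, kh - 1 - jh:kh - 1 - jh + H]
            ).reshape(N, Co, -1)
            for jh in range(kh)
        ])  # (kh, N, Co, V)
        dw[jd] = np.matmul(gys, xcol_t[None]).sum(axis=1)
    return np.ascontiguousarray(
        dw.reshape(kd, kh, Co, Ci, kw).transpose(2, 3, 0, 1, 4)
    )


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 3D cross-correlation (odd kernels only)."""
    x, weight = as_tensor(x), as_tensor(weight)
    k = weight.shape[2:]
    if any(s % 2 == 0 for s in k):
        raise ValueError("conv3d requires odd kernel sizes")
    if k == (1, 1, 1):
        w2 = weight.data.reshape(weight.shape[0], weight.shape[1])
        y = np.einsum("oi,nidhw->nodhw", w2, x.data)

        def backward(gy):
            gx = np.einsum("oi,nodhw->nidhw", w2, gy)
            gw = np.einsum("nodhw,nidhw->oi", gy, x.data).reshape(weight.shape)
            return gx.astype(x.data.dtype), gw.astype(weight.data.dtype)

        out = make_op(y.astype(x.data.dtype), (x, weight), backward)
    else:
        # one BLAS GEMM per kernel tap beats FFT up to 7^3 on AVX hardware
        use_fft = max(k) > 7
        corr = _fft_corr_same if use_fft else _gemm_corr_same
        wgrad = _fft_corr_weight_grad if use_fft else _gemm_corr_weight_grad
        y = corr(x.data, weight.data.astype(x.data.dtype))

        def backward(gy):
            wt = np.ascontiguousarray(
                np.flip(weight.data.transpose(1, 0, 2, 3, 4), (2, 3, 4))
            ).astype(gy.dtype)
            gx = corr(gy, wt)
            gw = wgrad(x.data.astype(gy.dtype), gy, k)
            return gx, gw.astype(weight.data.dtype)

        out = make_op(y, (x, weight), backward)
    if bias is not None:
        out = out + bias.reshape(1, -1, 1, 1, 1)
    return out


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 init_std: float | None = None):
        super().__init__()
        fan_in = c_in * kernel ** 3
        std = init_std if init_std is not None else float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_std: float | None = None):
        super().__init__()
        std = init_std if init_std is not None else float(np.sqrt(1.0 / d_in))
        self.weight = Parameter(rng.normal(0.0, std, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# -- pooling / resizing ---------------------------------------------------


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"max_pool3d needs even spatial dims, got {(D, H, W)}")
    xr = x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, D // 2, H // 2, W // 2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(gy):
        g = np.zeros_like(xr)
        np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, D, H, W)
        return (g,)

    return make_op(np.ascontiguousarray(y), (x,), backward)


def _resize_axis_weights(n_in: int, n_out: int):
    """Linear interpolation indices/weights, align_corners=False convention."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(np.int64), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    t = np.clip(src - np.floor(src), 0.0, 1.0)
    t = np.where(src < 0, 0.0, np.where(src > n_in - 1, 1.0, t))
    return i0, i1, t.astype(np.float32)


def upsample_trilinear_2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    plans = [
        (2 + ax, *_resize_axis_weights(s, 2 * s))
        for ax, s in enumerate((D, H, W))
    ]

    def apply(data):
        for ax, i0, i1, t in plans:
            sh = [1] * data.ndim
            sh[ax] = len(t)
            tt = t.reshape(sh)
            data = np.take(data, i0, axis=ax) * (1 - tt) + np.take(data, i1, axis=ax) * tt
        return data

    y = apply(x.data)

    def backward(gy):
        g = gy
        for ax, i0, i1, t in reversed(plans):
            sh = [1] * g.ndim
            sh[ax] = len(t)
            tt = t.reshape(sh)
            n_in = x.shape[ax]
            out = np.zeros(g.shape[:ax] + (n_in,) + g.shape[ax + 1:], dtype=g.dtype)
            gm = np.moveaxis(g, ax, 0)
            om = np.moveaxis(out, ax, 0)
            t0 = np.moveaxis(np.broadcast_to(1 - tt, g.shape), ax, 0)
            t1 = np.moveaxis(np.broadcast_to(tt, g.shape), ax, 0)
            np.add.at(om, i0, gm * t0)
            np.add.at(om, i1, gm * t1)
            g = out
        return (g,)

    return make_op(y.astype(x.data.dtype), (x,), backward)


# -- LSTM -----------------------------------------------------------------


class LSTM(Module):
    """Unidirectional multi-layer LSTM over a python-list sequence.

    Input: list of T tensors (N, d_in). Output: list of T tensors (N, hidden).
    """

    def __init__(self, d_in: int, hidden: int, layers: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.layers = layers
        cells = []
        for layer in range(layers):
            d = d_in if layer == 0 else hidden
            cell = Module()
            cell.w_ih = Parameter(rng.normal(0, np.sqrt(1.0 / d), (d, 4 * hidden)))
            cell.w_hh = Parameter(rng.normal(0, np.sqrt(1.0 / hidden), (hidden, 4 * hidden)))
            cell.bias = Parameter(np.zeros(4 * hidden))
            cells.append(cell)
        self.cells = cells

    def forward(self, xs: List[Tensor]) -> List[Tensor]:
        from ._autograd import concat

        hsz = self.hidden
        seq = xs
        n = seq[0].shape[0]
        for cell in self.cells:
            # input projection for all steps in one GEMM
            proj = concat(seq, axis=0) @ cell.w_ih
            h = Tensor(np.zeros((n, hsz), dtype=np.float32))
            c = Tensor(np.zeros((n, hsz), dtype=np.float32))
            out = []
            for step in range(len(seq)):
                gates = proj[step * n:(step + 1) * n] + h @ cell.w_hh + cell.bias
                i = gates[:, 0 * hsz:1 * hsz].sigmoid()
                f = gates[:, 1 * hsz:2 * hsz].sigmoid()
                g = gates[:, 2 * hsz:3 * hsz].tanh()
                o = gates[:, 3 * hsz:4 * hsz].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                out.append(h)
            seq = out
        return seq


# -- optimizer ------------------------------------------------------------


class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float):
        total = np.sqrt(sum(
            float((p.grad ** 2).sum()) for p in self.params if p.grad is not None
        ))
        if total > max_norm > 0:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
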