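"""Dual-encoder registration network.

Two weight-independent encoders (four conv blocks, three 2x2x2 max-poolings)
process the moving and fixed volumes. At each level the cross-modal
attention block enhances the feature pair; a 1x1x1 fusion convolution merges
the pair into a skip connection (and, at the deepest level, the bottleneck).
The decoder upsamples trilinearly, concatenates skips, refines at full
resolution, and a 3x3x3 head emits a 3-channel stationary velocity field,
which is integrated to a diffeomorphic displacement field and optionally
refined by the pseudo-temporal LSTM stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._autograd import Tensor, concat, no_grad
from .deform import jacobian_stats, vecint, warp
from .attention import CrossModalAttention, FuseConv
from .nn import Adam, Conv3d, Module, leaky_relu, max_pool3d, upsample_trilinear_2x
from .temporal import LstmRefiner, TaskMaskNet
from .volume_io import LabelMask, Volume

__all__ = ["NetConfig", "RegistrationResult", "RegistrationNetwork",
           "save_checkpoint", "load_checkpoint"]

_SLOPE = 0.2


@dataclass(frozen=True)
class NetConfig:
    grid_side: int = 32
    enc_channels: Tuple[int, ...] = (16, 32, 32, 32)
    dec_channels: Tuple[int, ...] = (32, 32, 32, 16)
    remaining_channels: Tuple[int, ...] = (32, 16, 16)
    vecint_steps: int = 7
    use_lstm: bool = True
    lstm_hidden: int = 128
    lstm_layers: int = 2
    lstm_residual: bool = True
    lstm_proj_dim: Optional[int] = None
    n_slices: int = 10
    gate_mode: str = "symmetric"
    enable_ecmca: bool = True
    enable_msfa: bool = True
    enable_dca: bool = True
    use_task_mask: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.enc_channels) != 4:
            raise ValueError("encoder must have exactly 4 levels")
        if self.grid_side % 8:
            raise ValueError("grid side must be divisible by 2**3 (three poolings)")
        if self.grid_side // 8 < 2:
            raise ValueError("deepest feature map would be smaller than 2 voxels")
        if self.use_lstm and self.n_slices > self.grid_side:
            raise ValueError("n_slices exceeds grid depth")


@dataclass
class RegistrationResult:
    warped_image: Volume
    warped_label: Optional[LabelMask]
    field: np.ndarray        # (3, D, H, W)
    velocity: np.ndarray     # (3, D, H, W)
    diagnostics: dict = field(default_factory=dict)


class ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(self.conv(x), _SLOPE)


class Encoder(Module):
    """Four conv blocks with 2x2x2 max-pooling between levels."""

    def __init__(self, channels, rng: np.random.Generator):
        super().__init__()
        blocks = []
        c_prev = 1
        for c in channels:
            blocks.append(ConvBlock(c_prev, c, rng))
            c_prev = c
        self.blocks = blocks

    def forward(self, x: Tensor) -> List[Tensor]:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"encoder expects (N,1,D,H,W), got {tuple(x.shape)}")
        feats = []
        for i, block in enumerate(self.blocks):
            if i > 0:
                x = max_pool3d(x)
            x = block(x)
            feats.append(x)
        return feats


class RegistrationNetwork(Module):
    def __init__(self, cfg: NetConfig = NetConfig()):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ec = cfg.enc_channels
        dc = cfg.dec_channels
        self.encoder_moving = Encoder(ec, rng)
        self.encoder_fixed = Encoder(ec, rng)
        if cfg.enable_ecmca:
            self.attn = [
                CrossModalAttention(
                    c, rng, gate_mode=cfg.gate_mode,
                    enable_msfa=cfg.enable_msfa, enable_dca=cfg.enable_dca,
                )
                for c in ec
            ]
        self.fuse = [FuseConv(2 * c, c, rng) for c in ec]

        # decoder: level 0 operates at bottleneck scale, then 3 upsamplings
        dec_blocks = []
        c_prev = ec[-1]
        for lvl, c_out in enumerate(dc):
            c_in = c_prev if lvl == 0 else c_prev + ec[-1 - lvl]
            dec_blocks.append(ConvBlock(c_in, c_out, rng))
            c_prev = c_out
        self.dec_blocks = dec_blocks
        rem_blocks = []
        for c_out in cfg.remaining_channels:
            rem_blocks.append(ConvBlock(c_prev, c_out, rng))
            c_prev = c_out
        self.rem_blocks = rem_blocks
        self._feature_channels = c_prev
        # near-identity start: tiny flow-head weights, zero bias
        self.flow_head = Conv3d(c_prev, 3, 3, rng, init_std=1e-5)

        if cfg.use_lstm:
            side = cfg.grid_side
            self.refiner = LstmRefiner(
                (side, side, side), rng, n_slices=cfg.n_slices,
                hidden=cfg.lstm_hidden, layers=cfg.lstm_layers,
                residual=cfg.lstm_residual, proj_dim=cfg.lstm_proj_dim,
            )
        if cfg.use_task_mask:
            self.task_mask_net = TaskMaskNet(c_prev, rng, n_slices=cfg.n_slices)

    # -- forward passes ---------------------------------------------------

    def encoder_forward(self, vol: Tensor) -> List[Tensor]:
        """Moving-stream encoder features, one map per level."""
        return self.encoder_moving(vol)

    def _decode(self, feats_m, feats_f):
        fused = []
        for lvl in range(4):
            fm, ff = feats_m[lvl], feats_f[lvl]
            if self.cfg.enable_ecmca:
                fm, ff = self.attn[lvl](fm, ff)
            fused.append(self.fuse[lvl](fm, ff))
        x = fused[-1]
        for lvl, block in enumerate(self.dec_blocks):
            if lvl > 0:
                x = upsample_trilinear_2x(x)
                x = concat([x, fused[3 - lvl]], axis=1)
            x = block(x)
        for block in self.rem_blocks:
            x = block(x)
        return x

    def forward_flow(self, moving: Tensor, fixed: Tensor,
                     return_features: bool = False):
        """Predict the stationary velocity field (N, 3, D, H, W)."""
        if tuple(moving.shape) != tuple(fixed.shape):
            raise ValueError(
                f"moving/fixed shape mismatch: {tuple(moving.shape)} vs "
                f"{tuple(fixed.shape)}"
            )
        feats_m = self.encoder_moving(moving)
        feats_f = self.encoder_fixed(fixed)
        features = self._decode(feats_m, feats_f)
        velocity = self.flow_head(features)
        if return_features:
            return velocity, features
        return velocity

    def predict_field(self, moving: Tensor, fixed: Tensor,
                      return_features: bool = False):
        """Velocity -> integrated (and optionally LSTM-refined) displacement."""
        velocity, features = self.forward_flow(moving, fixed, return_features=True)
        phi = vecint(velocity, self.cfg.vecint_steps)
        if self.cfg.use_lstm:
            phi = self.refiner(phi)
        if return_features:
            return velocity, phi, features
        return velocity, phi

    # -- inference --------------------------------------------------------

    def register(self, moving: Volume, fixed: Volume,
                 moving_mask: Optional[LabelMask] = None) -> RegistrationResult:
        if moving.data.shape != fixed.data.shape:
            raise ValueError(
                f"volumes share no grid: {moving.data.shape} vs {fixed.data.shape}"
            )
        with no_grad():
            mv = Tensor(moving.data.astype(np.float32)[None, None])
            fx = Tensor(fixed.data.astype(np.float32)[None, None])
            velocity_t, phi_t = self.predict_field(mv, fx)
        phi = phi_t.data[0].astype(np.float64)
        velocity = velocity_t.data[0].astype(np.float64)
        warped = warp(moving.data.astype(np.float64), phi, mode="trilinear")
        warped_label = None
        if moving_mask is not None:
            wl = warp(moving_mask.data, phi, mode="nearest")
            warped_label = LabelMask(wl.astype(np.uint8), moving_mask.spacing_mm)
        stats = jacobian_stats(phi)
        return RegistrationResult(
            warped_image=Volume(warped.astype(np.float32), moving.spacing_mm,
                                moving.modality),
            warped_label=warped_label,
            field=phi,
            velocity=velocity,
            diagnostics={"folding_fraction": stats["folding_fraction"]},
        )


# -- checkpointing --------------------------------------------------------


def save_checkpoint(model: RegistrationNetwork, path) -> None:
    state = model.state_dict()
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(model.cfg).items()}
    np.savez(path, __config__=json.dumps(cfg), **state)


def load_checkpoint(path) -> RegistrationNetwork:
    with np.load(path, allow_pickle=False) as archive:
        cfg_raw = json.loads(str(archive["__config__"]))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    for key in ("enc_channels", "dec_channels", "remaining_channels"):
        cfg_raw[key] = tuple(cfg_raw[key])
    cfg = NetConfig(**cfg_raw)
    model = RegistrationNetwork(cfg)
    model.load_state_dict(state)
    return model
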