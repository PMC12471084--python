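"""End-to-end training: dataset splitting, loss assembly, Adam loop.

The loss couples a soft-Dice term on the warped moving mask, a masked
negative-mutual-information term on the warped moving image, and a gradient
penalty on the displacement field. With the task mask enabled the Dice+MI
("registration") and gradient ("smoothness") terms are computed per depth
slab and combined through the learned per-slice weights; otherwise the plain
weighted sum over the full volume is used.

All randomness (parameter init, shuffling, phantom generation) flows from
the root seed, and the numpy compute stack is deterministic, so repeated
runs with one seed give identical loss histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ._autograd import Tensor, no_grad
from .deform import warp
from .network import NetConfig, RegistrationNetwork, save_checkpoint
from .objectives import LossWeights, dice_loss, grad_loss, mi_loss
from .phantom import PhantomCase, PhantomSpec, make_phantom_pair
from .temporal import masked_loss

__all__ = ["TrainConfig", "split_cases", "make_training_cases", "case_loss",
           "train"]

# softmax temperature for the z-scored task-mask training target
_MASK_TEMPERATURE = 1.0


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    epochs: int = 100
    batch_size: int = 1
    split: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    weights: LossWeights = field(default_factory=LossWeights)
    use_lstm: bool = True
    use_task_mask: bool = True
    seed: int = 0
    device: str = "cpu"
    grad_clip: float = 1.0
    restore_best: bool = True  # reload best-validation state after training
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if abs(sum(self.split) - 1.0) > 1e-6:
            raise ValueError(f"split must sum to 1, got {self.split}")

    def net_config(self) -> NetConfig:
        return replace(
            self.net, use_lstm=self.use_lstm, use_task_mask=self.use_task_mask,
            seed=self.seed,
        )


def split_cases(case_ids: Sequence, split=(0.70, 0.15, 0.15), seed: int = 0):
    """Deterministic shuffled partition into train/val/test id lists.

    Validation and test sizes are floored; the remainder goes to training.
    """
    ids = list(case_ids)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 cases to split, got {len(ids)}")
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError(f"split must sum to 1, got {split}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_val = int(np.floor(split[1] * len(ids)))
    n_test = int(np.floor(split[2] * len(ids)))
    n_train = len(ids) - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train:n_train + n_val],
        shuffled[n_train + n_val:],
    )


def make_training_cases(n_cases: int, base_spec: PhantomSpec, seed: int = 0,
                        share_anatomy: bool = False) -> List[PhantomCase]:
    """Seeded family of phantom pairs sharing the base spec.

    With ``share_anatomy`` the organ texture is identical across cases and
    only deformations and acquisition noise vary (the intra-patient motion
    setting); otherwise every case has its own anatomy.
    """
    anatomy = base_spec.seed if share_anatomy else None
    return [
        make_phantom_pair(
            replace(base_spec, seed=seed + 1000 * i, anatomy_seed=anatomy)
        )
        for i in range(n_cases)
    ]


def _case_tensors(case: PhantomCase):
    mv = Tensor(case.moving.data.astype(np.float32)[None, None])
    fx = Tensor(case.fixed.data.astype(np.float32)[None, None])
    mm = Tensor(case.moving_mask.data.astype(np.float32)[None, None])
    fm = Tensor(case.fixed_mask.data.astype(np.float32)[None, None])
    return mv, fx, mm, fm


def case_loss(model: RegistrationNetwork, case: PhantomCase,
              weights: LossWeights, use_task_mask: bool):
    """Loss tensor plus a dict of scalar diagnostics for one case."""
    mv, fx, mm, fm = _case_tensors(case)
    velocity, phi, features = model.predict_field(mv, fx, return_features=True)
    warped_img = warp(mv, phi)
    warped_mask = warp(mm, phi)
    # ROI fixed w.r.t. the prediction: a union with the *warped* mask makes
    # the MI voxel set prediction-dependent, and boundary-mismatch intensity
    # pairs then reward systematic under-deformation (observed empirically).
    roi = ndimage.binary_dilation(case.fixed_mask.data > 0.5, iterations=2)

    terms = {}
    if use_task_mask and model.cfg.use_task_mask:
        mask = model.task_mask_net(features)
        t_slices = model.cfg.n_slices
        d = phi.shape[2] // t_slices
        wi = warped_img.data[0, 0][roi]
        fi = fx.data[0, 0][roi]
        range_w = (float(wi.min()), float(wi.max()))
        range_f = (float(fi.min()), float(fi.max()))
        regs, smooths = [], []
        for t in range(t_slices):
            sl = slice(t * d, (t + 1) * d)
            dice_t = dice_loss(warped_mask[:, :, sl], fm[:, :, sl],
                               empty_is_zero=True)
            roi_slab = roi[sl]
            if roi_slab.sum() >= 32:  # slab histograms need enough samples
                mi_t = mi_loss(warped_img[0, 0, sl], fx[0, 0, sl], roi_slab,
                               range_a=range_w, range_b=range_f)
            else:
                mi_t = Tensor(np.float32(0.0))
            regs.append(weights.beta * dice_t + weights.gamma * mi_t)
            smooths.append(weights.alpha * grad_loss(phi[:, :, sl]))
        # The mask is detached in the weighting: letting gradients flow
        # through softmax-weighted task weights collapses onto the cheaper
        # task and the field shrinks to identity. The subnet instead learns
        # to up-weight, per slice, the task whose loss is high *relative to
        # its own across-slice distribution* (z-scored, so the negative MI
        # scale cannot bias the mix), via cross-entropy to that target.
        loss = masked_loss(Tensor(mask.data), regs, smooths)

        def zscore(vals):
            v = np.asarray(vals, dtype=np.float64)
            return (v - v.mean()) / (v.std() + 1e-8)

        target = np.stack(
            [zscore([float(r.data) for r in regs]),
             zscore([float(s.data) for s in smooths])], axis=-1,
        ) / _MASK_TEMPERATURE  # (T, 2)
        target = np.exp(target - target.max(axis=-1, keepdims=True))
        target /= target.sum(axis=-1, keepdims=True)
        ce = -(Tensor(target[None]) * (mask + 1e-12).log()).sum() * (
            1.0 / t_slices
        )
        loss = loss + 0.1 * ce
        terms["task_mask_mean_reg_weight"] = float(mask.data[..., 0].mean())
    else:
        dice = dice_loss(warped_mask, fm)
        mi = mi_loss(warped_img[0, 0], fx[0, 0], roi)
        grad = grad_loss(phi)
        loss = weights.alpha * grad + weights.beta * dice + weights.gamma * mi
        terms.update(
            dice=float(dice.data), mi=float(mi.data), grad=float(grad.data)
        )
    terms["loss"] = float(loss.data)
    return loss, terms


def _dataset_loss(model, cases, weights, use_task_mask) -> float:
    with no_grad():
        losses = [
            case_loss(model, c, weights, use_task_mask)[1]["loss"] for c in cases
        ]
    return float(np.mean(losses))


def train(cases: List[PhantomCase], cfg: TrainConfig,
          val_cases: Optional[List[PhantomCase]] = None,
          checkpoint_path=None, history_path=None,
          model: Optional[RegistrationNetwork] = None):
    """Adam training loop; returns (model, history).

    ``cases`` is the training split; validation defaults to the training set
    when no ``val_cases`` are given (toy-scale convenience). The state with
    the best validation loss is restored into the returned model. Raises on
    non-finite loss.
    """
    if not cases:
        raise ValueError("empty training set")
    from .nn import Adam  # local import avoids cycle at module load

    if model is None:
        model = RegistrationNetwork(cfg.net_config())
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    val = val_cases if val_cases else cases
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(cases))
        epoch_losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = order[b0:b0 + cfg.batch_size]
            opt.zero_grad()
            for i in batch:
                loss, terms = case_loss(model, cases[i], cfg.weights,
                                        cfg.use_task_mask)
                if not np.isfinite(terms["loss"]):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={terms['loss']}"
                    )
                (loss * (1.0 / len(batch))).backward()
                epoch_losses.append(terms["loss"])
            if cfg.grad_clip > 0:
                opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
        val_loss = _dataset_loss(model, val, cfg.weights, cfg.use_task_mask)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
        }
        history.append(row)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    if cfg.restore_best:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    if history_path is not None:
        with open(history_path, "w") as fh:
            for row in history:
                fh.write(json.dumps(row) + "\n")
    return model, history
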