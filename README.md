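# prostreg

Cross-modal deformable registration of MRI-like and TRUS-like prostate
volumes, exercised end to end on synthetic phantoms with known ground-truth
deformations.

The registration model is a dual-encoder 3D U-Net with cross-modal channel
attention at every encoder level (multi-scale 3/5/7 aggregation, dynamic
channel attention, and a voxel-wise cross-modal sigmoid gate), 1x1x1 fusion
convolutions for skips and bottleneck, a 3-channel velocity head integrated
to a diffeomorphic displacement by seven scaling-and-squaring steps, and an
optional pseudo-temporal LSTM stage that refines the field depth-slice by
depth-slice. Training minimizes a composite objective: gradient smoothness
(weight 0.4), soft Dice on warped masks (1.0), and negative Parzen-window
mutual information inside the prostate ROI (1.0), optionally re-weighted per
depth slice by a learned two-task mask.

Everything runs on plain numpy/scipy: the network is built on a small
reverse-mode autodiff engine in `prostreg._autograd` (convolutions as
per-tap BLAS GEMMs, differentiable trilinear warping, max pooling, trilinear
upsampling, LSTM). No GPU or deep-learning framework is required.

## Command-line interface

```sh
# generate phantom cases (NIfTI volumes/masks, CSV landmarks, 4D NIfTI field)
prostreg phantom --out data/ --shape 32 --seed 0 --cases 4

# train on generated phantoms and save a checkpoint
prostreg train --out model.npz --cases 8 --shape 32 --epochs 10 --seed 0

# register one pair
prostreg register --moving data/case_000/moving.nii.gz \
                  --fixed data/case_000/fixed.nii.gz \
                  --moving-mask data/case_000/moving_mask.nii.gz \
                  --ckpt model.npz --out pred/case_000

# per-case and aggregate metrics (DSC, robust DSC, TRE, robust TRE,
# folding fraction, success rate)
prostreg evaluate --pred pred/ --ref data/ --out metrics.csv
```

`prostreg train --config config.yaml` overrides any training field
(`lr`, `epochs`, `weights: {alpha, beta, gamma}`, `use_lstm`,
`use_task_mask`, nested `net:` fields such as `gate_mode` or
`enable_ecmca`), which is how the ablation configurations are run.

## Layout

| Module | Contents |
| --- | --- |
| `prostreg.phantom` | synthetic cross-modal pairs, velocity fields, 4D sequences |
| `prostreg.volume_io` | NIfTI/CSV I/O, resampling, depth crop, ROI masking |
| `prostreg.deform` | warp, composition, scaling-and-squaring, Jacobian stats |
| `prostreg.attention` | multi-scale aggregation, channel attention, cross-modal gate, fusion |
| `prostreg.network` | dual encoders, decoder, flow head, checkpointing |
| `prostreg.temporal` | depth slicing, LSTM refinement, task mask |
| `prostreg.objectives` | Dice / mutual-information / gradient losses |
| `prostreg.evaluation` | DSC, TRE, robust aggregates, success rate |
| `prostreg.training` | splitting, Adam loop, history logging |
| `prostreg.cli` | `prostreg` command group |
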