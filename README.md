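# endostitch

Unsupervised two-stage image stitching for endoscopic frames.

Endoscopes (cystoscopes in particular) have a narrow field of view; mapping a
hollow organ's surface means stitching many overlapping frames into one
mosaic.  Classical feature-based stitching (ORB + RANSAC and relatives)
degrades badly on endoscopic imagery — weak texture, blur, lighting drift —
and supervised learning needs labelled medical data that rarely exists.
`endostitch` implements a stitcher that trains **without labels**, from pairs
of overlapping frames alone, aimed at researchers studying endoscopic
mosaicking pipelines and at anyone who needs a fully inspectable,
NumPy-based reference implementation of unsupervised deep homography
estimation and seam-aware fusion.

## Method

Two stages, both trained unsupervised:

1. **Alignment.**  A pair of normalised frames is stacked into an
   `[H, W, 2C]` tensor.  A shared convolutional extractor builds feature
   pyramids at 1/2, 1/4 and 1/8 resolution; local feature correlation plus a
   regression head predicts, coarse to fine, residual updates to the
   *4-point parameterisation* — the displacements `(Δx_k, Δy_k)` of the four
   target-frame corners.  A differentiable **tensor DLT** converts the
   displacements to the homography `H` (with `H[2,2] = 1`) mapping target
   into reference coordinates.  Training minimises the multiscale
   **photometric ablation loss**

   `L = Σ_s w_s · ‖ W_H(I_tgt) − M_H ⊙ I_ref ‖₁ / |M_H|`

   evaluated in both warp directions, where `W_H` is bilinear backward
   warping and `M_H` the warped footprint mask.
2. **Warping + fusion.**  The *double-H transformer* places both frames on a
   shared black canvas (reference by an integer translation `T`, target by
   `T·H`).  A two-branch fusion network — a low-resolution pixelisation
   deformation branch (3 pooling + 3 transposed-convolution stages) plus a
   full-resolution refinement branch (3 convolutions + 8 residual
   combination blocks) — blends the canvas into one mosaic, constrained by
   **content masks** (non-overlap regions must reproduce the sources) and a
   **seam mask** (gradient consistency across the smoothed overlap).

Stitch outcomes are auto-labelled *success / failure / error*: geometric
sanity checks on `H`, plus a block-matching self-check that measures the
residual misalignment between the aligned images and extrapolates it to the
frame corners.  Mosaics are scored with PSNR, RMSE, SSIM and total variation.

Because no public cystoscopy dataset is deposited, the package ships a
synthetic generator producing endoscope-like pairs (reddish mucosa texture,
vessel-like curves, circular vignette, brightness jitter, blur) with known
ground-truth homographies and controlled overlap grades (small < 40 %,
medium 40–80 %, large > 80 %).  The networks run on a small pure-NumPy
autograd engine (`endostitch.nn`), so everything trains and runs on one CPU.

## Worked example

```python
import numpy as np
from endostitch import experiments as ex
from endostitch import make_dataset, stitch, evaluate_stitch

# unsupervised pre-training: 64 noiseless synthetic pairs, 300 Adam steps
aligner = ex.train_scaled_aligner(seed=1, n_train=64, steps=300)
rec = ex.alignment_recovery_benchmark(aligner, seed=1, n_test=16)
print(f"corner error: {rec['mean_corner_error_px']:.2f} px "
      f"(identity baseline {rec['identity_baseline_px']:.2f} px, "
      f"ratio {rec['error_ratio']:.2f})")

fusion = ex.train_scaled_fusion(aligner, seed=1, n_train=16, steps=200)
samples, _ = make_dataset(ex.recovery_conditions(42, 1))
s = samples[0]
out, est, label, canvas = stitch((s.reference, s.target), aligner, fusion)
print(f"outcome: {label.label}")
print(f"estimated corner offsets (px): {np.round(est.total_offsets, 1)}")
report = evaluate_stitch(out, canvas)
print(f"overlap-region PSNR {report.psnr:.1f} dB, SSIM {report.ssim:.3f}, "
      f"TV {report.tv:.4f}")
```

Output:

```
corner error: 3.21 px (identity baseline 14.49 px, ratio 0.22)
outcome: success
estimated corner offsets (px): [-6.1  6.7 -8.6  6.3 -6.9  8.  -7.7  4.6]
overlap-region PSNR 30.9 dB, SSIM 0.882, TV 0.0033
```

The 300-step model already recovers the held-out homographies to ~3 px mean
corner error versus a ~14.5 px do-nothing baseline; the fused mosaic matches
the aligned reference at 31 dB over the overlap.  The test suite trains for
1,500 steps and reaches correspondingly lower errors.

A `click` CLI wraps the same pipeline (`endostitch generate-data /
train-align / finetune-align / train-fuse / stitch / evaluate`); run
`endostitch --help` for the flags.  Checkpoints are single `.npz` files with
an embedded config hash.

## Layout

```
src/endostitch/
  nn/           NumPy autograd engine: conv, pooling, grid sampling,
                correlation, differentiable DLT, Adam
  synthetic.py  endoscope-like pair generator, overlap grades, manifests
  geometry.py   homography algebra, exact overlap rates, DLT oracles
  alignment.py  multiscale homography network (HomographyAligner)
  warping.py    double-H canvas warping
  fusion.py     masks + two-branch fusion network (SeamFusion)
  quality.py    block-matching residual-misalignment self-check
  metrics.py    PSNR / RMSE / SSIM / TV
  pipeline.py   two-phase training, stitching, outcome taxonomy, reports
  experiments.py scaled-down benchmark experiments
  cli.py        command-line interface
docs/methods.md model details, parameter choices, limitations
```
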