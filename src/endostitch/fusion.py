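"""Mask-constrained two-branch fusion of aligned image pairs.

Given a warped canvas from the double-H transformer, a low-resolution
*pixelisation deformation* branch (three pooling stages, three transposed
convolutions) learns the blending rules, while a full-resolution *refinement*
branch (three convolutions plus eight residual combination blocks) restores
detail as an additive correction.  Training is unsupervised, constrained by

* **content masks** — each image's footprint minus the overlap, where the
  fused mosaic must reproduce the original pixels;
* a **seam mask** — the overlap region with Gaussian-smoothed edges, where
  the fused gradients must follow both sources, suppressing visible seams;
* a low-weight overlap photometric term anchoring the intensity level of the
  fused overlap to the mean of the two aligned sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .nn import ops
from .warping import WarpedCanvas

__all__ = [
    "MaskSet",
    "StitchOutput",
    "build_masks",
    "deformation_branch",
    "refinement_branch",
    "fuse",
    "fusion_loss",
    "hard_cut_composite",
    "average_blend",
    "seam_band",
    "FusionNet",
    "SeamFusion",
]


@dataclass
class MaskSet:
    content_reference: np.ndarray  # {0,1}: reference-only footprint
    content_target: np.ndarray  # {0,1}: target-only footprint
    seam: np.ndarray  # [0,1]: overlap, edge-smoothed


@dataclass
class StitchOutput:
    fused: np.ndarray  # canvas-sized mosaic in [0,1]
    low_res: np.ndarray  # deformation-branch output
    residual: np.ndarray  # refinement-branch correction


def build_masks(canvas: WarpedCanvas, seam_sigma: float = 5.0) -> MaskSet:
    """Content masks (footprint minus overlap) and the smoothed seam mask."""
    overlap = canvas.overlap_mask
    if overlap.sum() == 0:
        warnings.warn("empty overlap: seam mask is all zero", stacklevel=2)
        seam = np.zeros_like(overlap)
    else:
        seam = gaussian_filter(overlap.astype(np.float64), sigma=seam_sigma)
        seam = np.clip(seam, 0.0, 1.0).astype(np.float32) * np.maximum(
            canvas.mask_reference, canvas.mask_target
        )
        seam = np.maximum(seam, overlap)  # interior of the overlap stays 1
    return MaskSet(
        content_reference=(canvas.mask_reference * (1 - overlap)).astype(np.float32),
        content_target=(canvas.mask_target * (1 - overlap)).astype(np.float32),
        seam=seam.astype(np.float32),
    )


def hard_cut_composite(canvas: WarpedCanvas) -> np.ndarray:
    """Reference pixels where available, target elsewhere (visible seam)."""
    m = canvas.mask_reference[:, :, None]
    return canvas.warped_reference * m + canvas.warped_target * (1 - m) * (
        canvas.mask_target[:, :, None]
    )


def average_blend(canvas: WarpedCanvas) -> np.ndarray:
    """Mask-weighted mean of the two warped images on the union footprint."""
    wsum = canvas.mask_reference + canvas.mask_target
    num = (
        canvas.warped_reference * canvas.mask_reference[:, :, None]
        + canvas.warped_target * canvas.mask_target[:, :, None]
    )
    return num / np.maximum(wsum, 1e-8)[:, :, None]


def seam_band(canvas: WarpedCanvas, width: int = 5) -> np.ndarray:
    """Pixels within ``width`` px of the overlap boundary, inside the union."""
    overlap = canvas.overlap_mask > 0.5
    if not overlap.any():
        return np.zeros_like(canvas.mask_reference, dtype=bool)
    inner = binary_dilation(~overlap) & overlap  # boundary pixels
    band = binary_dilation(inner, iterations=width)
    union = (canvas.mask_reference + canvas.mask_target) > 0.5
    return band & union


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class FusionNet(nn.Module):
    """Two-branch fusion network.

    Input is the 8-channel canvas stack (both warped RGB images and both
    footprint masks); the refinement branch additionally sees the upsampled
    deformation output.
    """

    def __init__(self, in_channels: int = 8, deform_widths=(16, 24, 32),
                 refine_width: int = 8, n_blocks: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = deform_widths
        rw = refine_width
        self.d1 = nn.Conv2d(in_channels, w1, rng=rng)
        self.d2 = nn.Conv2d(w1, w2, rng=rng)
        self.d3 = nn.Conv2d(w2, w3, rng=rng)
        self.u1 = nn.ConvTranspose2d(w3, w2, rng=rng)
        self.u2 = nn.ConvTranspose2d(w2, w1, rng=rng)
        self.u3 = nn.ConvTranspose2d(w1, w1, rng=rng)
        self.dout = nn.Conv2d(w1, 3, rng=rng)
        self.r1 = nn.Conv2d(in_channels + 3, rw, rng=rng)
        self.r2 = nn.Conv2d(rw, rw, rng=rng)
        self.r3 = nn.Conv2d(rw, rw, rng=rng)
        self.blocks = [
            (nn.Conv2d(rw, rw, rng=rng), nn.Conv2d(rw, rw, rng=rng))
            for _ in range(n_blocks)
        ]
        self.rout = nn.Conv2d(rw, 3, zero_init=True)

    def deformation(self, x: nn.Tensor) -> nn.Tensor:
        h = ops.avg_pool2d(self.d1(x).leaky_relu())
        h = ops.avg_pool2d(self.d2(h).leaky_relu())
        h = ops.avg_pool2d(self.d3(h).leaky_relu())
        h = self.u1(h).leaky_relu()
        h = self.u2(h).leaky_relu()
        h = self.u3(h).leaky_relu()
        return self.dout(h).sigmoid()

    def refinement(self, x: nn.Tensor, low_up: nn.Tensor) -> nn.Tensor:
        h = self.r1(nn.concat([x, low_up], axis=1)).leaky_relu()
        h = self.r2(h).leaky_relu()
        h = self.r3(h).leaky_relu()
        for ca, cb in self.blocks:
            h = h + cb(ca(h).leaky_relu())
            h = h.leaky_relu()
        return self.rout(h)


def _canvas_tensor(canvas: WarpedCanvas) -> np.ndarray:
    return np.concatenate(
        [
            canvas.warped_reference,
            canvas.warped_target,
            canvas.mask_reference[:, :, None],
            canvas.mask_target[:, :, None],
        ],
        axis=2,
    ).transpose(2, 0, 1)[None].astype(np.float32)


def _pad_to(x: np.ndarray, mult: int = 8):
    n, c, h, w = x.shape
    hp = int(np.ceil(h / mult)) * mult
    wp = int(np.ceil(w / mult)) * mult
    if (hp, wp) == (h, w):
        return x, (h, w)
    return np.pad(x, ((0, 0), (0, 0), (0, hp - h), (0, wp - w))), (h, w)


def _working_factor(h: int, w: int, max_side: int) -> int:
    f = 1
    while max(h, w) / f > max_side:
        f *= 2
    return f


def _forward(net: FusionNet, canvas: WarpedCanvas, max_side: int = 256):
    """Run both branches; returns (fused, low, residual) tensors on the padded
    grid plus the crop shape."""
    x = nn.Tensor(_pad_to(_canvas_tensor(canvas))[0])
    hw = canvas.warped_reference.shape[:2]
    f = _working_factor(*x.shape[2:], max_side)
    xl = x
    for _ in range(int(np.log2(f))):
        xl = ops.avg_pool2d(xl)
    low = net.deformation(xl)
    low_up = ops.resize_bilinear(low, x.shape[2:]) if f > 1 else low
    residual = net.refinement(x, low_up)
    fused = (low_up + residual).clip01()
    return fused, low, residual, xl, hw


def fuse(canvas: WarpedCanvas, net: FusionNet, max_side: int = 256) -> StitchOutput:
    """Fuse a warped canvas into a mosaic (numpy interface)."""
    fused, low, residual, _, (h, w) = _forward(net, canvas, max_side)
    crop = lambda t: t.data[0, :, :h, :w].transpose(1, 2, 0)
    return StitchOutput(fused=crop(fused), low_res=crop(low), residual=crop(residual))


def deformation_branch(canvas: WarpedCanvas, net: FusionNet, max_side: int = 256) -> np.ndarray:
    """Low-resolution fused estimate from the pooling/transposed-conv branch."""
    return fuse(canvas, net, max_side).low_res


def refinement_branch(canvas: WarpedCanvas, low_res: np.ndarray, net: FusionNet) -> np.ndarray:
    """Full-resolution residual correction given the low-res fusion."""
    x = nn.Tensor(_pad_to(_canvas_tensor(canvas))[0])
    lr = nn.Tensor(
        _pad_to(low_res.transpose(2, 0, 1)[None].astype(np.float32))[0]
    )
    if lr.shape[2:] != x.shape[2:]:
        lr = ops.resize_bilinear(lr, x.shape[2:])
    h, w = canvas.warped_reference.shape[:2]
    return net.refinement(x, lr).data[0, :, :h, :w].transpose(1, 2, 0)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _grad_terms(img: nn.Tensor, axis: int):
    if axis == 3:
        return img[:, :, :, 1:] - img[:, :, :, :-1]
    return img[:, :, 1:, :] - img[:, :, :-1, :]


def _masked_l1(a: nn.Tensor, b: nn.Tensor, m: nn.Tensor):
    area = float(m.data.sum())
    if area < 1.0:
        return None
    return ((a - b) * m).abs().sum() / (area * a.shape[1])


def _loss_terms(fused, wref, wtgt, mref, mtgt, cref, ctgt, seam,
                content_weight, seam_weight, overlap_weight):
    terms = []
    for src, cmask in ((wref, cref), (wtgt, ctgt)):
        t = _masked_l1(fused, src, cmask)
        if t is not None:
            terms.append(t * content_weight)
    for src, fmask in ((wref, mref), (wtgt, mtgt)):
        w = seam * fmask
        area = float(w.data.sum())
        if area < 1.0:
            continue
        for axis in (2, 3):
            wg = w[:, :, : w.shape[2] - (axis == 2), : w.shape[3] - (axis == 3)]
            gdiff = (_grad_terms(fused, axis) - _grad_terms(src, axis)).abs()
            terms.append((gdiff * wg).sum() / (area * fused.shape[1]) * (seam_weight / 2))
    both = mref * mtgt
    area = float(both.data.sum())
    if area >= 1.0 and overlap_weight > 0:
        avg = (wref + wtgt) * 0.5
        terms.append(
            ((fused - avg) * both).abs().sum() / (area * fused.shape[1]) * overlap_weight
        )
    if not terms:
        warnings.warn("all masks empty; fusion loss is zero", stacklevel=2)
        return nn.Tensor(np.zeros(()))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def _tensor_masks(canvas: WarpedCanvas, masks: MaskSet, pad_hw):
    def prep(m):
        arr = np.zeros((1, 1) + pad_hw, dtype=np.float32)
        arr[0, 0, : m.shape[0], : m.shape[1]] = m
        return nn.Tensor(arr)

    return tuple(
        prep(m)
        for m in (
            canvas.mask_reference,
            canvas.mask_target,
            masks.content_reference,
            masks.content_target,
            masks.seam,
        )
    )


def _training_loss(net, canvas, masks, max_side, content_weight, seam_weight,
                   overlap_weight):
    """Content + seam + overlap terms, applied at both branch resolutions."""
    fused, low, _, xl, _ = _forward(net, canvas, max_side)
    pad_hw = fused.shape[2:]
    x = nn.Tensor(_pad_to(_canvas_tensor(canvas))[0])
    wref, wtgt = x[:, 0:3], x[:, 3:6]
    mref, mtgt, cref, ctgt, seam = _tensor_masks(canvas, masks, pad_hw)
    loss = _loss_terms(fused, wref, wtgt, mref, mtgt, cref, ctgt, seam,
                       content_weight, seam_weight, overlap_weight)
    if low.shape[2:] != pad_hw:
        k = pad_hw[0] // low.shape[2]
        pool = lambda t: _avg_pool_k(t, k)
        loss = loss + _loss_terms(
            low, xl[:, 0:3], xl[:, 3:6], pool(mref), pool(mtgt), pool(cref),
            pool(ctgt), pool(seam), content_weight, seam_weight, overlap_weight
        )
    else:
        loss = loss + _loss_terms(low, wref, wtgt, mref, mtgt, cref, ctgt, seam,
                                  content_weight, seam_weight, overlap_weight)
    return loss


def _avg_pool_k(t: nn.Tensor, k: int) -> nn.Tensor:
    while k > 1:
        t = ops.avg_pool2d(t)
        k //= 2
    return t


def fusion_loss(out: StitchOutput, canvas: WarpedCanvas, masks: MaskSet,
                content_weight: float = 1.0, seam_weight: float = 0.5,
                overlap_weight: float = 0.25) -> float:
    """Numpy interface: loss of a fused mosaic given canvas and masks."""
    h, w = canvas.warped_reference.shape[:2]
    fused = nn.Tensor(out.fused.transpose(2, 0, 1)[None].astype(np.float32))
    x = nn.Tensor(_canvas_tensor(canvas))
    mref, mtgt, cref, ctgt, seam = _tensor_masks(canvas, masks, (h, w))
    return float(
        _loss_terms(fused, x[:, 0:3], x[:, 3:6], mref, mtgt, cref, ctgt, seam,
                    content_weight, seam_weight, overlap_weight).item()
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SeamFusion(BaseEstimator, TransformerMixin):
    """Seam-aware unsupervised fusion estimator.

    ``fit`` takes a list of :class:`WarpedCanvas` objects (variable sizes; one
    canvas per optimisation step) and trains both branches with Adam under
    per-epoch exponential learning-rate decay.  ``transform`` fuses canvases
    into :class:`StitchOutput` mosaics.
    """

    def __init__(
        self,
        deform_widths=(16, 24, 32),
        refine_width=8,
        n_blocks=8,
        content_weight=1.0,
        seam_weight=0.5,
        overlap_weight=0.25,
        seam_sigma=5.0,
        max_side=256,
        lr=1e-4,
        lr_decay=0.97,
        n_epochs=80,
        max_steps=None,
        warm_start=False,
        seed=0,
        verbose=0,
    ):
        self.deform_widths = deform_widths
        self.refine_width = refine_width
        self.n_blocks = n_blocks
        self.content_weight = content_weight
        self.seam_weight = seam_weight
        self.overlap_weight = overlap_weight
        self.seam_sigma = seam_sigma
        self.max_side = max_side
        self.lr = lr
        self.lr_decay = lr_decay
        self.n_epochs = n_epochs
        self.max_steps = max_steps
        self.warm_start = warm_start
        self.seed = seed
        self.verbose = verbose

    def _ensure_model(self):
        if self.warm_start and hasattr(self, "model_"):
            return
        self.model_ = FusionNet(
            deform_widths=self.deform_widths,
            refine_width=self.refine_width,
            n_blocks=self.n_blocks,
            seed=self.seed,
        )
        self.loss_history_ = []
        self.n_steps_ = 0
        self._opt_state = None

    def fit(self, X, y=None):
        canvases = list(X)
        if not canvases:
            raise ValueError("empty dataset")
        self._ensure_model()
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        if self._opt_state is not None:
            opt.m, opt.v, opt.t = self._opt_state
        rng = np.random.default_rng(self.seed + 1)
        mask_sets = [build_masks(c, self.seam_sigma) for c in canvases]
        done = False
        for epoch in range(self.n_epochs):
            opt.lr = self.lr * self.lr_decay**epoch
            for i in rng.permutation(len(canvases)):
                loss = _training_loss(
                    self.model_, canvases[i], mask_sets[i], self.max_side,
                    self.content_weight, self.seam_weight, self.overlap_weight,
                )
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(f"non-finite fusion loss: {loss.item()}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.loss_history_.append(float(loss.item()))
                self.n_steps_ += 1
                if self.max_steps is not None and self.n_steps_ >= self.max_steps:
                    done = True
                    break
            if self.verbose:
                print(f"epoch {epoch}: loss={self.loss_history_[-1]:.5f}")
            if done:
                break
        self._opt_state = (opt.m, opt.v, opt.t)
        return self

    def transform(self, X):
        if isinstance(X, WarpedCanvas):
            return fuse(X, self.model_, self.max_side)
        return [fuse(c, self.model_, self.max_side) for c in X]
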