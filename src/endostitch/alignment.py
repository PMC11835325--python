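"""Unsupervised multiscale homography estimation.

A shared-weight convolutional extractor builds feature pyramids at 1/2, 1/4
and 1/8 resolution for both images of a stacked pair.  Going coarse to fine,
local feature correlation followed by a small regression head predicts a
residual update to the four corner displacements; the running displacement is
converted to a homography by the differentiable tensor DLT, which is also used
to warp the finer-level target features toward the reference before the next
correlation.  Training needs no labels: the photometric ablation loss compares
the warped target against the reference masked by the warped footprint, at
every pyramid scale.

The :class:`HomographyAligner` estimator wraps network construction, the Adam
training loop with per-epoch exponential learning-rate decay, and prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import ops

__all__ = [
    "stack_pair",
    "build_feature_pyramid",
    "correlate",
    "regress_offsets",
    "tensor_dlt",
    "ablation_loss",
    "multiscale_alignment_loss",
    "estimate_homography",
    "HomographyEstimate",
    "AlignmentNet",
    "HomographyAligner",
]

#: pyramid scale factors, fine to coarse
SCALES = (2, 4, 8)


def stack_pair(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Stack two normalised images along channels into an [H,W,2C] tensor."""
    reference = np.asarray(reference, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if reference.shape != target.shape:
        raise ValueError("reference and target must have identical shapes")
    for img in (reference, target):
        if img.min() < -1e-6 or img.max() > 1.0 + 1e-6:
            raise ValueError("images must be normalised to [0, 1]")
    if reference.ndim == 2:
        reference, target = reference[:, :, None], target[:, :, None]
    return np.concatenate([reference, target], axis=2)


def _check_size(h: int, w: int):
    if h % 8 or w % 8:
        raise ValueError(f"spatial dims ({h},{w}) must be divisible by 8")


class AlignmentNet(nn.Module):
    """Backbone + per-scale regression heads.

    Eight convolutional layers produce 16/24/32-channel maps at 1/2, 1/4 and
    1/8 resolution; each pyramid level has a correlation window radius and a
    conv + adaptive-pool + fully-connected head emitting 8 numbers (the
    residual corner offsets, in full-resolution pixels).
    """

    def __init__(self, in_channels: int = 3, widths=(16, 24, 32), radii=(2, 2, 4),
                 gain_div: float = 8.0, seed: int = 0):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = widths
        self.radii = tuple(radii)
        self.in_channels = in_channels
        self.gain_div = gain_div
        self.c1a = nn.Conv2d(in_channels, w1, stride=2, rng=rng)
        self.c1b = nn.Conv2d(w1, w1, rng=rng)
        self.c2a = nn.Conv2d(w1, w2, stride=2, rng=rng)
        self.c2b = nn.Conv2d(w2, w2, rng=rng)
        self.c2c = nn.Conv2d(w2, w2, rng=rng)
        self.c3a = nn.Conv2d(w2, w3, stride=2, rng=rng)
        self.c3b = nn.Conv2d(w3, w3, rng=rng)
        self.c3c = nn.Conv2d(w3, w3, rng=rng)
        self.heads = []
        for r in self.radii:
            d = (2 * r + 1) ** 2
            self.heads.append(_Head(d, hidden=32, fc_hidden=64, rng=rng))

    def features(self, x: nn.Tensor):
        """Three-level pyramid for one C-channel image batch (NCHW)."""
        f1 = self.c1b(self.c1a(x).leaky_relu()).leaky_relu()
        f2 = self.c2c(self.c2b(self.c2a(f1).leaky_relu()).leaky_relu()).leaky_relu()
        f3 = self.c3c(self.c3b(self.c3a(f2).leaky_relu()).leaky_relu()).leaky_relu()
        return [f1, f2, f3]


class _Head(nn.Module):
    """Correlation volume → 8 residual corner offsets (zero at init).

    Two contributions are summed: a convolutional + fully connected regression
    on the learned-feature correlation volume (final layer zero-initialised)
    and a gated patch-matching estimate (see :func:`_ncc_corners`) computed
    from the images themselves.  The gate starts at zero, so the untrained
    head emits exactly zero offsets; ``_GATE_SCALE`` puts a useful gate value
    within reach of a few dozen Adam steps.
    """

    _GATE_SCALE = 64.0

    def __init__(self, in_ch: int, hidden: int, fc_hidden: int, rng):
        self.conv1 = nn.Conv2d(in_ch, hidden, stride=2, rng=rng)
        self.conv2 = nn.Conv2d(hidden, hidden, stride=2, rng=rng)
        self.fc1 = nn.Linear(hidden * 16, fc_hidden, rng=rng)
        self.fc2 = nn.Linear(fc_hidden, 8, zero_init=True)
        self.gate = nn.Parameter(np.zeros(1))

    def __call__(self, corr: nn.Tensor, gain: float, ncc_corners: nn.Tensor) -> nn.Tensor:
        h = self.conv2(self.conv1(corr).leaky_relu()).leaky_relu()
        h = ops.adaptive_avg_pool2d(h, (4, 4))
        n = h.shape[0]
        h = h.transpose(0, 2, 3, 1).reshape(n, -1)
        learned = self.fc2(self.fc1(h).leaky_relu()) * gain
        return learned + ncc_corners * (self.gate * self._GATE_SCALE)


#: fixed 3x3 zero-mean patch-extraction kernel (identity taps minus the mean)
_PATCH_KERNEL = (np.eye(9).reshape(9, 1, 3, 3) - 1.0 / 9.0).astype(np.float32)
_ZERO9 = np.zeros(9, dtype=np.float32)
_NCC_TEMPERATURE = 20.0


def _ncc_corners(gray_ref: nn.Tensor, gray_tgt: nn.Tensor, radius: int,
                 scale: int) -> nn.Tensor:
    """Differentiable patch-matching corner-offset estimate at one level.

    Zero-mean 3x3 patches of the two (grayscale, pooled, target pre-warped by
    the running estimate) images are unit-normalised and correlated in a
    ±radius window; a soft-argmax over the window gives the expected residual
    displacement per position, which is averaged over the four spatial
    quadrants and assigned to the matching corners.  The correlation peaks at
    the *negative* of the corner-offset convention (the target content that
    matches a reference position p lies at p − offset), hence the sign flip.
    """
    wk = nn.Tensor(_PATCH_KERNEL)
    bk = nn.Tensor(_ZERO9)
    fr = ops.l2_normalize(ops.conv2d(gray_ref, wk, bk))
    ft = ops.l2_normalize(ops.conv2d(gray_tgt, wk, bk))
    corr = ops.local_correlation(fr, ft, radius)
    p = (corr * _NCC_TEMPERATURE).softmax(axis=1)
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    fscale = -float(scale)  # sign flip + level pixels → full-resolution pixels
    ex = (p * (dx.reshape(1, -1, 1, 1) * fscale).astype(np.float32)).sum(
        axis=1, keepdims=True
    )
    ey = (p * (dy.reshape(1, -1, 1, 1) * fscale).astype(np.float32)).sum(
        axis=1, keepdims=True
    )
    quad = ops.adaptive_avg_pool2d(nn.concat([ex, ey], axis=1), (2, 2))
    n = quad.shape[0]
    qf = quad.reshape(n, 2, 4)  # spatial bins raveled: TL, TR, BL, BR
    return nn.concat([qf[:, :, 0], qf[:, :, 1], qf[:, :, 3], qf[:, :, 2]], axis=1)


# ---------------------------------------------------------------------------
# functional pieces (spec operations)
# ---------------------------------------------------------------------------

def build_feature_pyramid(x: np.ndarray, net: AlignmentNet | None = None):
    """Feature maps at 1/2, 1/4, 1/8 resolution for an [H,W,C] image.

    Deterministic given fixed network weights; a fresh seeded network is built
    when none is supplied.
    """
    x = np.asarray(x, dtype=np.float32)
    _check_size(*x.shape[:2])
    net = net or AlignmentNet(in_channels=x.shape[2] if x.ndim == 3 else 1)
    xt = nn.Tensor(x.transpose(2, 0, 1)[None])
    return [f.data[0].transpose(1, 2, 0) for f in net.features(xt)]


def correlate(f_ref: np.ndarray, f_tgt: np.ndarray, radius: int = 4) -> np.ndarray:
    """Windowed cosine correlation volume between two [H,W,C] feature maps."""
    if f_ref.shape != f_tgt.shape:
        raise ValueError("feature maps must share spatial dims")
    a = nn.Tensor(np.asarray(f_ref, np.float32).transpose(2, 0, 1)[None])
    b = nn.Tensor(np.asarray(f_tgt, np.float32).transpose(2, 0, 1)[None])
    out = ops.local_correlation(ops.l2_normalize(a), ops.l2_normalize(b), radius)
    return out.data[0].transpose(1, 2, 0)


def regress_offsets(corr: np.ndarray, head: _Head | None = None, gain: float = 16.0) -> np.ndarray:
    """Map a correlation volume to 8 corner-offset numbers (zero-init head → 0)."""
    corr = np.asarray(corr, np.float32)
    d = corr.shape[2]
    if head is None:
        head = _Head(d, 32, 64, rng=np.random.default_rng(0))
    ncc = nn.Tensor(np.zeros((1, 8), dtype=np.float32))
    out = head(nn.Tensor(corr.transpose(2, 0, 1)[None]), gain, ncc)
    return out.data[0]


def tensor_dlt(offsets: np.ndarray, size: int) -> np.ndarray:
    """Corner offsets → homography (differentiable solve; numpy interface)."""
    off = np.asarray(offsets, dtype=np.float64).reshape(1, 8)
    from . import geometry

    return geometry.homography_from_offsets(off, size)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _abl(warped_target: nn.Tensor, reference: nn.Tensor, mask: nn.Tensor) -> nn.Tensor:
    if float(mask.data.sum()) < 1.0:
        raise ValueError("degenerate overlap: empty warped footprint")
    c = reference.shape[1]
    diff = (warped_target - reference * mask).abs()
    # the area normaliser stays in the graph: its gradient penalises
    # footprint shrinkage
    return diff.sum() / (mask.sum() * float(c))


def ablation_loss(warped_target, reference, warped_mask) -> float:
    """Mean |warped target − mask-ablated reference| over the valid footprint.

    Accepts [H,W,C] numpy arrays (mask [H,W]); zero iff the images agree on
    the mask support.
    """
    wt = nn.Tensor(np.asarray(warped_target, np.float32).transpose(2, 0, 1)[None])
    ref = nn.Tensor(np.asarray(reference, np.float32).transpose(2, 0, 1)[None])
    m = nn.Tensor(np.asarray(warped_mask, np.float32)[None, None])
    return float(_abl(wt, ref, m).item())


def _scale_matrix(scale: int) -> np.ndarray:
    """Full-resolution → 1/scale level coordinates (pixel-centre convention)."""
    s = 1.0 / scale
    off = s / 2.0 - 0.5
    return np.array([[s, 0, off], [0, s, off], [0, 0, 1.0]])


def _forward(net: AlignmentNet, x: nn.Tensor, offset_clamp: float):
    """Coarse-to-fine pass. Returns (per_scale residuals, running clamped
    offsets per level coarse→fine, final offsets, final H)."""
    n, twoc, h, w = x.shape
    _check_size(h, w)
    c = net.in_channels
    size = h
    gain = size / net.gain_div
    # run both halves of every stacked pair through the shared extractor as
    # one batch of 2N images
    both = x.reshape(n, 2, c, h, w).reshape(2 * n, c, h, w)
    f_both = net.features(both)
    f_ref = [f[0::2] for f in f_both]
    f_tgt = [f[1::2] for f in f_both]
    # pooled grayscale pyramids feed the fixed patch-matching estimator
    gray = {}
    g = x.reshape(n, 2, c, h, w).mean(axis=2).reshape(2 * n, 1, h, w)
    for k in (1, 2, 3):
        g = ops.avg_pool2d(g)
        gray[k] = (g[0::2], g[1::2])
    total = nn.Tensor(np.zeros((n, 8), dtype=np.float32))
    residuals, runnings, levels = [], [], []
    for level in (2, 1, 0):  # coarse → fine
        scale = SCALES[level]
        fr = ops.l2_normalize(f_ref[level])
        ft = f_tgt[level]
        gr, gt = gray[level + 1]
        if np.any(total.data):
            hcur = ops.dlt_solve(total, size)
            a = _scale_matrix(scale)
            grid = ops.homography_grid(
                hcur, ft.shape[2:], pre=a, post=np.linalg.inv(a), invert=True
            )
            warped = ops.grid_sample(nn.concat([ft, gt], axis=1), grid)
            ft, gt = warped[:, :-1], warped[:, -1:]
        ft = ops.l2_normalize(ft)
        corr = ops.local_correlation(fr, ft, net.radii[level])
        ncc = _ncc_corners(gr, gt, net.radii[level], scale)
        res = net.heads[level](corr, gain, ncc)
        residuals.append(res)
        total = (total + res).clamp_st(offset_clamp)
        runnings.append(total)
        levels.append(level)
    hfin = ops.dlt_solve(total, size)
    return residuals, runnings, levels, total, hfin


def multiscale_alignment_loss(
    x: nn.Tensor,
    net: AlignmentNet,
    offset_clamp: float,
    loss_weights=(1.0, 2.0, 4.0),
):
    """Sum of per-scale bidirectional ablation losses for the running estimates.

    ``loss_weights`` are ordered fine→coarse; the coarse terms dominate early
    training, when only the widest correlation window sees the true motion.
    The photometric term is evaluated in both warp directions (target→reference
    through H and reference→target through H⁻¹): a purely one-sided,
    area-normalised ablation loss admits a degenerate optimum where the
    network shrinks the warped footprint onto featureless regions, and the
    reverse direction removes it.
    """
    n, twoc, h, w = x.shape
    c = net.in_channels
    ref_full, tgt_full = x[:, :c], x[:, c:]
    _, runnings, levels, total, hfin = _forward(net, x, offset_clamp)
    ones = nn.Tensor(np.ones((n, 1, h, w), dtype=np.float32))
    loss = None
    for running, level in zip(runnings, levels):
        scale = SCALES[level]
        k = int(np.log2(scale))
        ref_l, tgt_l, ones_l = ref_full, tgt_full, ones
        for _ in range(k):
            ref_l = ops.avg_pool2d(ref_l)
            tgt_l = ops.avg_pool2d(tgt_l)
            ones_l = ops.avg_pool2d(ones_l)
        hcur = ops.dlt_solve(running, h)
        a = _scale_matrix(scale)
        a_inv = np.linalg.inv(a)
        term = None
        for invert, src_l, dst_l in (
            (True, tgt_l, ref_l),  # warp target into the reference frame
            (False, ref_l, tgt_l),  # warp reference into the target frame
        ):
            grid = ops.homography_grid(
                hcur, dst_l.shape[2:], pre=a, post=a_inv, invert=invert
            )
            warped = ops.grid_sample(nn.concat([src_l, ones_l], axis=1), grid)
            piece = _abl(warped[:, :c], dst_l, warped[:, c : c + 1]) * 0.5
            term = piece if term is None else term + piece
        term = term * float(loss_weights[level])
        loss = term if loss is None else loss + term
    return loss, total, hfin


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

@dataclass
class HomographyEstimate:
    per_scale_offsets: list  # coarse→fine residuals, full-resolution pixels
    total_offsets: np.ndarray  # (8,)
    h: np.ndarray  # (3,3), h[2,2] == 1


class HomographyAligner(BaseEstimator):
    """Unsupervised deep homography estimator (fit on stacked image pairs).

    Parameters follow the training recipe of the two-phase schedule: Adam with
    an initial learning rate decayed exponentially per epoch.  ``X`` is an
    array of shape (n_pairs, H, W, 2C) of channel-stacked normalised pairs;
    no labels are used.

    Attributes (after fit): ``model_``, ``loss_history_`` (per step),
    ``epoch_losses_``, ``n_steps_``.
    """

    def __init__(
        self,
        widths=(16, 24, 32),
        radii=(2, 2, 4),
        gain_div=32.0,
        offset_clamp_frac=0.25,
        loss_weights=(1.0, 2.0, 4.0),
        lr=1e-4,
        lr_decay=0.97,
        batch_size=8,
        n_epochs=120,
        max_steps=None,
        warm_start=False,
        seed=0,
        verbose=0,
    ):
        self.widths = widths
        self.radii = radii
        self.gain_div = gain_div
        self.offset_clamp_frac = offset_clamp_frac
        self.loss_weights = loss_weights
        self.lr = lr
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.max_steps = max_steps
        self.warm_start = warm_start
        self.seed = seed
        self.verbose = verbose

    # -- internal ------------------------------------------------------------
    def _validate_x(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] % 2:
            raise ValueError("X must be (n_pairs, H, W, 2C)")
        _check_size(X.shape[1], X.shape[2])
        return X

    def _ensure_model(self, in_channels):
        if self.warm_start and hasattr(self, "model_"):
            return
        self.model_ = AlignmentNet(
            in_channels=in_channels,
            widths=self.widths,
            radii=self.radii,
            gain_div=self.gain_div,
            seed=self.seed,
        )
        self.loss_history_ = []
        self.epoch_losses_ = []
        self.n_steps_ = 0
        self._opt_state = None

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y=None):
        X = self._validate_x(X)
        if len(X) == 0:
            raise ValueError("empty dataset")
        n, h, w, twoc = X.shape
        self._ensure_model(twoc // 2)
        clamp = self.offset_clamp_frac * h
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        if self._opt_state is not None:
            opt.m, opt.v, opt.t = self._opt_state
        rng = np.random.default_rng(self.seed + 1)
        xs = X.transpose(0, 3, 1, 2)  # NCHW
        steps_per_epoch = max(1, int(np.ceil(n / self.batch_size)))
        done = False
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            opt.lr = self.lr * self.lr_decay**epoch
            epoch_loss = []
            for b in range(steps_per_epoch):
                idx = order[b * self.batch_size : (b + 1) * self.batch_size]
                if len(idx) == 0:
                    continue
                batch = nn.Tensor(xs[idx])
                loss, _, _ = multiscale_alignment_loss(
                    batch, self.model_, clamp, self.loss_weights
                )
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"non-finite loss at step {self.n_steps_}: {loss.item()}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                self.loss_history_.append(float(loss.item()))
                epoch_loss.append(float(loss.item()))
                self.n_steps_ += 1
                if self.max_steps is not None and self.n_steps_ >= self.max_steps:
                    done = True
                    break
            if epoch_loss:
                self.epoch_losses_.append(float(np.mean(epoch_loss)))
            if self.verbose:
                print(f"epoch {epoch}: loss={self.epoch_losses_[-1]:.5f} lr={opt.lr:.2e}")
            if done:
                break
        self._opt_state = (opt.m, opt.v, opt.t)
        return self

    def _estimates(self, X):
        X = self._validate_x(X)
        n, h, w, twoc = X.shape
        clamp = self.offset_clamp_frac * h
        out = []
        bs = max(1, self.batch_size)
        for i in range(0, n, bs):
            batch = nn.Tensor(X[i : i + bs].transpose(0, 3, 1, 2))
            residuals, _, _, total, hfin = _forward(self.model_, batch, clamp)
            for j in range(batch.shape[0]):
                out.append(
                    HomographyEstimate(
                        per_scale_offsets=[r.data[j].copy() for r in residuals],
                        total_offsets=total.data[j].astype(np.float64),
                        h=hfin.data[j].astype(np.float64),
                    )
                )
        return out

    def predict(self, X) -> np.ndarray:
        """Homography matrices (n, 3, 3) for stacked pairs X."""
        return np.stack([e.h for e in self._estimates(X)])

    def predict_offsets(self, X) -> np.ndarray:
        return np.stack([e.total_offsets for e in self._estimates(X)])


def estimate_homography(pair, aligner: HomographyAligner) -> HomographyEstimate:
    """Run the full coarse-to-fine estimate for one (reference, target) pair."""
    x = stack_pair(*pair)[None]
    return aligner._estimates(x)[0]
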