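"""Self-check of alignment quality by staged block-matching registration.

Given a warped canvas, the residual misalignment between the two aligned
images is measured without ground truth: zero-mean 3x3 patch descriptors are
matched in a local window (normalised cross-correlation with sub-pixel
parabolic refinement), a residual affine transform is fitted to the flow by
iteratively reweighted least squares, the target is corrected and the
procedure repeats coarse-to-fine (1/4 → 1/2 → full resolution).  The composed
transform, extrapolated to the reference-frame corners, estimates the mean
corner misalignment in pixels; the final stage's inlier fraction measures
flow coherence (badly misaligned pairs produce incoherent matches).

Both numbers feed the automated outcome classifier: large extrapolated
residual or incoherent flow marks a failed stitch.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import affine_transform, binary_erosion

from . import geometry
from .nn import Tensor
from .nn.ops import conv2d, l2_normalize, local_correlation

__all__ = ["measure_residual_misalignment"]

#: fixed 3x3 zero-mean patch-extraction kernel
_PATCH_KERNEL = (np.eye(9).reshape(9, 1, 3, 3) - 1.0 / 9.0).astype(np.float32)
_ZERO9 = np.zeros(9, dtype=np.float32)

#: (pool level k, search radius) per registration stage, coarse → fine
_STAGES = ((2, 6), (1, 3), (0, 2))


def _pool(im: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return im
    h, w = im.shape
    h2, w2 = h - h % 2**k, w - w % 2**k
    im = im[:h2, :w2]
    for _ in range(k):
        im = im.reshape(im.shape[0] // 2, 2, im.shape[1] // 2, 2).mean(axis=(1, 3))
    return im


def _flow_affine(ga, gb, ov, k, r, min_pts=40, return_matches=False):
    """One matching stage; returns (2x3 affine of content displacement,
    inlier fraction[, matches]) or None when the overlap has too few textured
    points.  ``matches`` are (x, y, u, v, weight) arrays in full-res pixels."""
    gap, gbp, ovp = _pool(ga, k), _pool(gb, k), _pool(ov, k)
    wk, bk = Tensor(_PATCH_KERNEL), Tensor(_ZERO9)
    fa_raw = conv2d(Tensor(gap[None, None].astype(np.float32)), wk, bk)
    fb_raw = conv2d(Tensor(gbp[None, None].astype(np.float32)), wk, bk)
    tex = np.sqrt((fa_raw.data[0] ** 2).sum(axis=0))
    fa, fb = l2_normalize(fa_raw), l2_normalize(fb_raw)
    m = binary_erosion(ovp > 0.9, iterations=2)
    if m.sum() < min_pts:
        return None
    sel = m & (tex > np.quantile(tex[m], 0.6))
    if sel.sum() < min_pts:
        return None

    side = 2 * r + 1
    corr = local_correlation(fa, fb, r).data[0]
    cs = corr.reshape(side * side, *corr.shape[1:])[:, sel]
    am = np.argmax(cs, axis=0)
    peak = cs[am, np.arange(cs.shape[1])]
    iy, ix = np.unravel_index(am, (side, side))
    dys = (iy - r).astype(np.float64)
    dxs = (ix - r).astype(np.float64)
    # parabolic sub-pixel refinement along both axes
    for i in range(cs.shape[1]):
        j, kx = iy[i], ix[i]
        if 0 < j < side - 1:
            v0, v1, v2 = cs[(j - 1) * side + kx, i], cs[j * side + kx, i], cs[(j + 1) * side + kx, i]
            den = 2 * (v0 - 2 * v1 + v2)
            if abs(den) > 1e-12:
                dys[i] += np.clip((v0 - v2) / den, -0.5, 0.5)
        if 0 < kx < side - 1:
            v0, v1, v2 = cs[j * side + kx - 1, i], cs[j * side + kx, i], cs[j * side + kx + 1, i]
            den = 2 * (v0 - 2 * v1 + v2)
            if abs(den) > 1e-12:
                dxs[i] += np.clip((v0 - v2) / den, -0.5, 0.5)

    yy, xx = np.nonzero(sel)
    x = (xx + 0.5) * 2**k - 0.5
    y = (yy + 0.5) * 2**k - 0.5
    # matched target content for reference position p sits at p − offset
    u = -dxs * 2**k
    v = -dys * 2**k
    w0 = tex[sel] * np.clip(peak, 0, None)
    w = w0.copy()
    a0 = np.stack([x, y, np.ones_like(x)], axis=1)
    for _ in range(4):  # IRLS with a Cauchy-style weight
        aw = a0 * w[:, None]
        cu, *_ = np.linalg.lstsq(aw, u * w, rcond=None)
        cv, *_ = np.linalg.lstsq(aw, v * w, rcond=None)
        rr = np.hypot(a0 @ cu - u, a0 @ cv - v)
        sig = max(np.median(rr) * 1.48, 0.3 * 2**k)
        w = w0 / (1 + (rr / (2.0 * sig)) ** 2)
    inlier = float((rr < max(1.5 * 2**k, 1.5)).mean())
    if return_matches:
        return np.stack([cu, cv]), inlier, (x, y, u, v, w)
    return np.stack([cu, cv]), inlier


def _apply_correction(im: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Resample `im` so its content moves by the affine displacement field."""
    a = np.eye(3)
    a[0] += m[0]
    a[1] += m[1]
    ai = np.linalg.inv(a)
    mat = np.array([[ai[1, 1], ai[1, 0]], [ai[0, 1], ai[0, 0]]])
    off = np.array([ai[1, 2], ai[0, 2]])
    return affine_transform(im, mat, offset=off, order=1, mode="constant", cval=0.0)


def _projective_from_matches(x, y, u, v, w, total_affine):
    """Weighted IRLS homography fit to the composed correspondences.

    The last matching stage measured residual flow (u, v) after the affine
    corrections ``total_affine`` were applied to the target, so the original
    target position of the content matching reference position p is
    ``A⁻¹(p − (u, v))``; G maps those positions back onto the reference.
    """
    ai = np.linalg.inv(total_affine)
    q = np.stack([x - u, y - v, np.ones_like(x)], axis=1) @ ai.T
    src = q[:, :2] / q[:, 2:3]
    dst = np.stack([x, y], axis=1)
    # similarity normalisation for conditioning
    c = src.mean(axis=0)
    s = max(np.abs(src - c).max(), 1.0)
    n = np.array([[1 / s, 0, -c[0] / s], [0, 1 / s, -c[1] / s], [0, 0, 1]])
    sn = (src - c) / s
    dn = (dst - c) / s
    ww = w.copy()
    g = None
    for _ in range(3):
        rows, rhs, wr = [], [], []
        for (xs, ys), (xd, yd) in zip(sn, dn):
            rows.append([xs, ys, 1, 0, 0, 0, -xs * xd, -ys * xd])
            rhs.append(xd)
            rows.append([0, 0, 0, xs, ys, 1, -xs * yd, -ys * yd])
            rhs.append(yd)
        a = np.asarray(rows)
        b = np.asarray(rhs)
        wv = np.repeat(ww, 2)
        try:
            h8, *_ = np.linalg.lstsq(a * wv[:, None], b * wv, rcond=None)
        except np.linalg.LinAlgError:
            return None
        g = np.concatenate([h8, [1.0]]).reshape(3, 3)
        pred = np.stack([sn[:, 0], sn[:, 1], np.ones(len(sn))], axis=1) @ g.T
        pred = pred[:, :2] / pred[:, 2:3]
        rr = np.hypot(*(pred - dn).T)
        sig = max(np.median(rr) * 1.48, 1e-3)
        ww = w / (1 + (rr / (2.0 * sig)) ** 2)
    return np.linalg.inv(n) @ g @ n


def measure_residual_misalignment(canvas, frame_size: int):
    """Estimate (mean corner misalignment px, flow coherence) for a canvas.

    Residual misalignment is the mean displacement the fitted residual
    transform assigns to the four reference-frame corners — the same summary
    the 5-px ground-truth rule applies to the estimated homography.  A final
    projective fit captures perspective residuals that grow toward the
    corners; it falls back to the composed affine when ill-conditioned.
    Returns ``(inf, 0.0)`` when the overlap is too small or featureless.
    """
    ga = canvas.warped_reference.mean(axis=2).astype(np.float64)
    gb = canvas.warped_target.mean(axis=2).astype(np.float64)
    ov = canvas.overlap_mask.astype(np.float64)
    total = np.eye(3)
    gb_cur, ov_cur = gb, ov
    coherence = 0.0
    matches = None
    for i, (k, r) in enumerate(_STAGES):
        last = i == len(_STAGES) - 1
        res = _flow_affine(ga, gb_cur, ov_cur, k, r, return_matches=last)
        if res is None:
            return float("inf"), 0.0
        if last:
            m, coherence, matches = res
        else:
            m, coherence = res
        a = np.eye(3)
        a[0] += m[0]
        a[1] += m[1]
        if not last:
            gb_cur = _apply_correction(gb_cur, m)
            ov_cur = (_apply_correction(ov_cur, m) > 0.99).astype(np.float64) * (
                ov > 0.5
            )
        total = a @ total
    tx, ty = canvas.spec.translation
    corners = np.c_[
        geometry.corner_points(frame_size) + np.array([tx, ty]), np.ones(4)
    ]
    moved = corners @ total.T
    d = moved[:, :2] / moved[:, 2:3] - corners[:, :2]
    affine_est = float(np.mean(np.hypot(d[:, 0], d[:, 1])))

    # total here includes the last affine stage; the projective fit replaces
    # that last stage, so compose matches with the affine of the stages before
    prior = np.linalg.inv(
        np.eye(3) + np.vstack([m, np.zeros((1, 3))])
    ) @ total
    g = _projective_from_matches(*matches, prior)
    if g is None:
        return affine_est, coherence
    gm = corners @ g.T
    dg = gm[:, :2] / gm[:, 2:3] - corners[:, :2]
    proj_est = float(np.mean(np.hypot(dg[:, 0], dg[:, 1])))
    # distrust a projective fit that wildly disagrees with the affine one
    if not np.isfinite(proj_est) or proj_est > 4 * affine_est + 8.0:
        return affine_est, coherence
    return proj_est, coherence
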