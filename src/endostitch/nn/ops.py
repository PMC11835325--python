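"""Array operations with custom backward passes.

Everything here operates on NCHW tensors.  The two non-standard ops are
``dlt_solve`` (the differentiable direct linear transform that turns four
corner displacements into a homography via an 8x8 linear system) and
``homography_grid`` (per-pixel projective sampling coordinates with a
gradient with respect to the homography), which together let photometric
losses back-propagate into corner-offset regression.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Tensor, _node

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "adaptive_avg_pool2d",
    "grid_sample",
    "resize_bilinear",
    "local_correlation",
    "l2_normalize",
    "dlt_solve",
    "homography_grid",
]


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    # channels-last windowing keeps the patch gather cache-friendly
    xp = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * c)
    return cols, oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation). w: (Cout, Cin, kh, kw)."""
    n, c, h, wd = x.shape
    cout, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = np.ascontiguousarray(
        w.data.transpose(0, 2, 3, 1).reshape(cout, kh * kw * cin)
    )
    y = cols @ wmat.T + b.data
    out = np.ascontiguousarray(y.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2))

    def bwd(g):
        gy = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * oh * ow, cout)
        if w.requires_grad:
            dw = (gy.T @ cols).reshape(cout, kh, kw, cin).transpose(0, 3, 1, 2)
            w._accum(np.ascontiguousarray(dw))
        if b.requires_grad:
            b._accum(gy.sum(axis=0))
        if x.requires_grad:
            if stride == 1 and oh == h and ow == wd:
                # full convolution of the upstream gradient with the
                # spatially flipped kernel: one GEMM instead of k*k
                # strided scatter-adds
                gcols, _, _ = _im2col(g, kh, kw, 1, kh // 2)
                wflip = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1]
                    .transpose(1, 2, 3, 0)
                    .reshape(cin, kh * kw * cout)
                )
                dx = (gcols @ wflip.T).reshape(n, h, wd, cin)
                x._accum(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
            else:
                dcols = (gy @ wmat).reshape(n, oh, ow, kh, kw, c)
                hp, wp = h + 2 * pad, wd + 2 * pad
                dxp = np.zeros((n, hp, wp, c), dtype=x.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[
                            :, i : i + stride * oh : stride, j : j + stride * ow : stride
                        ] += dcols[:, :, :, i, j]
                x._accum(
                    np.ascontiguousarray(
                        dxp[:, pad : pad + h, pad : pad + wd].transpose(0, 3, 1, 2)
                    )
                )

    return _node(out.astype(x.dtype, copy=False), (x, w, b), bwd)


def _dilate2(x: Tensor) -> Tensor:
    """Insert zeros between pixels (stride-2 zero stuffing)."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, 2 * h - 1, 2 * w - 1), dtype=x.dtype)
    out[:, :, ::2, ::2] = x.data

    def bwd(g):
        x._accum(np.ascontiguousarray(g[:, :, ::2, ::2]))

    return _node(out, (x,), bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution, fixed kernel 4, stride 2, pad 1 (exact 2x upsample).

    w: (Cin, Cout, 4, 4); output spatial dims are exactly twice the input's.
    Implemented as zero-dilation followed by an ordinary convolution with the
    spatially flipped kernel, which shares the fast im2col path (and its
    backward) with :func:`conv2d`.
    """
    n, cin, h, wd = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin_w != cin:
        raise ValueError("conv_transpose2d channel mismatch")
    wf = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]  # (Cout, Cin, kh, kw), flipped
    return conv2d(_dilate2(x), wf, b, stride=1, pad=kh - 1 - 1)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: dims ({h},{w}) not divisible by {k}")
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bwd(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)

    return _node(y, (x,), bwd)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple) -> Tensor:
    n, c, h, w = x.shape
    oh, ow = out_hw
    hs = [(int(np.floor(i * h / oh)), int(np.ceil((i + 1) * h / oh))) for i in range(oh)]
    ws = [(int(np.floor(j * w / ow)), int(np.ceil((j + 1) * w / ow))) for j in range(ow)]
    y = np.empty((n, c, oh, ow), dtype=x.dtype)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            y[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bwd(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                dx[:, :, h0:h1, w0:w1] += (
                    g[:, :, i : i + 1, j : j + 1] / ((h1 - h0) * (w1 - w0))
                )
        x._accum(dx)

    return _node(y, (x,), bwd)


# ---------------------------------------------------------------------------
# bilinear sampling
# ---------------------------------------------------------------------------

def grid_sample(x: Tensor, grid: Tensor, padding: str = "zeros") -> Tensor:
    """Bilinear sampling of `x` (N,C,H,W) at `grid` (N,2,Hg,Wg) pixel coords.

    grid[:,0] holds x (column) and grid[:,1] y (row) coordinates in the input
    frame.  ``zeros`` padding treats everything outside the image as 0 and is
    differentiable w.r.t. both arguments; ``border`` clamps coordinates and is
    used only for constant resampling grids.
    """
    n, c, h, w = x.shape
    _, two, hg, wg = grid.shape
    if two != 2:
        raise ValueError("grid must have 2 coordinate channels")
    p = hg * wg
    gx = grid.data[:, 0].reshape(n, p).astype(np.float64)
    gy = grid.data[:, 1].reshape(n, p).astype(np.float64)
    if padding == "border":
        if grid.requires_grad:
            raise NotImplementedError("border padding has no grid gradient")
        gx = np.clip(gx, 0.0, w - 1.0)
        gy = np.clip(gy, 0.0, h - 1.0)
    elif padding != "zeros":
        raise ValueError(padding)

    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    fx = (gx - x0).astype(x.dtype)
    fy = (gy - y0).astype(x.dtype)

    corners = []  # (idx_flat, weight, valid)
    for dy in (0, 1):
        for dx in (0, 1):
            xi, yi = x0 + dx, y0 + dy
            valid = ((xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)).astype(x.dtype)
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy) * valid
            idx = np.clip(yi, 0, h - 1) * w + np.clip(xi, 0, w - 1)
            corners.append((idx, wgt, valid))

    xf = x.data.reshape(n, c, h * w)
    out = np.zeros((n, c, p), dtype=x.dtype)
    gathered = []
    for idx, wgt, valid in corners:
        vals = np.take_along_axis(xf, idx[:, None, :].repeat(c, axis=1), axis=2)
        vals = vals * valid[:, None, :]
        gathered.append(vals)
        out += wgt[:, None, :] * vals
    out = out.reshape(n, c, hg, wg)

    def bwd(g):
        gg = g.reshape(n, c, p)
        if x.requires_grad:
            dxf = np.zeros((n, h * w, c), dtype=x.dtype)
            for (idx, wgt, valid), _ in zip(corners, gathered):
                vals = (wgt[:, None, :] * gg).transpose(0, 2, 1)  # (N,P,C)
                for b_ in range(n):
                    np.add.at(dxf[b_], idx[b_], vals[b_])
            x._accum(dxf.transpose(0, 2, 1).reshape(x.shape))
        if grid.requires_grad:
            v00, v01, v10, v11 = gathered  # (dy,dx) = (0,0),(0,1),(1,0),(1,1)
            dout_dgx = (1 - fy)[:, None, :] * (v01 - v00) + fy[:, None, :] * (v11 - v10)
            dout_dgy = (1 - fx)[:, None, :] * (v10 - v00) + fx[:, None, :] * (v11 - v01)
            dgx = (gg * dout_dgx).sum(axis=1)
            dgy = (gg * dout_dgy).sum(axis=1)
            dgrid = np.stack([dgx, dgy], axis=1).reshape(n, 2, hg, wg)
            grid._accum(dgrid.astype(grid.dtype, copy=False))

    return _node(out, (x, grid), bwd)


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Bilinear resize with half-pixel-centre convention, border padding."""
    n, c, h, w = x.shape
    oh, ow = out_hw
    jj, ii = np.meshgrid(np.arange(ow), np.arange(oh))
    gx = (jj + 0.5) * (w / ow) - 0.5
    gy = (ii + 0.5) * (h / oh) - 0.5
    grid = Tensor(
        np.broadcast_to(
            np.stack([gx, gy], axis=0)[None].astype(x.dtype), (n, 2, oh, ow)
        ).copy()
    )
    return grid_sample(x, grid, padding="border")


# ---------------------------------------------------------------------------
# feature correlation
# ---------------------------------------------------------------------------

def l2_normalize(x: Tensor, eps: float = 1e-8) -> Tensor:
    """Unit-normalise feature vectors along the channel axis."""
    norm = np.sqrt((x.data**2).sum(axis=1, keepdims=True) + eps)
    y = x.data / norm

    def bwd(g):
        x._accum((g - y * (g * y).sum(axis=1, keepdims=True)) / norm)

    return _node(y, (x,), bwd)


def local_correlation(f_ref: Tensor, f_tgt: Tensor, radius: int) -> Tensor:
    """Inner products between f_ref and shifted f_tgt in a (2r+1)^2 window.

    Output (N, (2r+1)^2, H, W); displacement d = (dy+r)*(2r+1)+(dx+r).
    """
    if f_ref.shape != f_tgt.shape:
        raise ValueError("correlation: feature shapes differ")
    n, c, h, w = f_ref.shape
    r = radius
    side = 2 * r + 1
    ftp = np.pad(f_tgt.data, ((0, 0), (0, 0), (r, r), (r, r)))
    out = np.empty((n, side * side, h, w), dtype=f_ref.dtype)
    d = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = ftp[:, :, r + dy : r + dy + h, r + dx : r + dx + w]
            out[:, d] = (f_ref.data * shifted).sum(axis=1)
            d += 1

    def bwd(g):
        if f_ref.requires_grad:
            dref = np.zeros_like(f_ref.data)
            d_ = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    shifted = ftp[:, :, r + dy : r + dy + h, r + dx : r + dx + w]
                    dref += g[:, d_ : d_ + 1] * shifted
                    d_ += 1
            f_ref._accum(dref)
        if f_tgt.requires_grad:
            dtp = np.zeros_like(ftp)
            d_ = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    dtp[:, :, r + dy : r + dy + h, r + dx : r + dx + w] += (
                        g[:, d_ : d_ + 1] * f_ref.data
                    )
                    d_ += 1
            f_tgt._accum(dtp[:, :, r : r + h, r : r + w])

    return _node(out, (f_ref, f_tgt), bwd)


# ---------------------------------------------------------------------------
# differentiable homography machinery
# ---------------------------------------------------------------------------

def _dlt_system(offsets: np.ndarray, size: int):
    """Build the 8x8 DLT system for corners (0,0),(s-1,0),(s-1,s-1),(0,s-1)."""
    n = offsets.shape[0]
    s = float(size - 1)
    base = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=np.float64)
    disp = base[None] + offsets.reshape(n, 4, 2).astype(np.float64)
    a = np.zeros((n, 8, 8), dtype=np.float64)
    b = np.zeros((n, 8), dtype=np.float64)
    for k in range(4):
        x, y = base[k]
        u, v = disp[:, k, 0], disp[:, k, 1]
        a[:, 2 * k, 0:3] = [x, y, 1.0]
        a[:, 2 * k, 6] = -x * u
        a[:, 2 * k, 7] = -y * u
        b[:, 2 * k] = u
        a[:, 2 * k + 1, 3:6] = [x, y, 1.0]
        a[:, 2 * k + 1, 6] = -x * v
        a[:, 2 * k + 1, 7] = -y * v
        b[:, 2 * k + 1] = v
    return a, b, base


def dlt_solve(offsets: Tensor, size: int) -> Tensor:
    """Corner offsets (N,8; order TL,TR,BR,BL ×(dx,dy)) → homographies (N,3,3).

    The returned matrix maps the four base corners of a ``size``-pixel square
    exactly onto their displaced positions, with H[2,2]=1.  Solved in float64
    as a batched 8x8 linear system; the backward pass uses the standard
    adjoint of the solve.
    """
    n = offsets.shape[0]
    a, b, base = _dlt_system(offsets.data, size)
    h8 = np.linalg.solve(a, b[..., None])[..., 0]
    hm = np.concatenate([h8, np.ones((n, 1))], axis=1).reshape(n, 3, 3)

    def bwd(g):
        gh = g.reshape(n, 9)[:, :8].astype(np.float64)
        lam = np.linalg.solve(a.transpose(0, 2, 1), gh[..., None])[..., 0]  # dL/db
        # dL/dA = -lam h^T; A depends on (u,v) only in columns 6,7
        dof = np.zeros((n, 8))
        for k in range(4):
            x, y = base[k]
            da6 = -lam[:, 2 * k] * h8[:, 6]
            da7 = -lam[:, 2 * k] * h8[:, 7]
            dof[:, 2 * k] = lam[:, 2 * k] + da6 * (-x) + da7 * (-y)
            da6 = -lam[:, 2 * k + 1] * h8[:, 6]
            da7 = -lam[:, 2 * k + 1] * h8[:, 7]
            dof[:, 2 * k + 1] = lam[:, 2 * k + 1] + da6 * (-x) + da7 * (-y)
        offsets._accum(dof.astype(offsets.dtype, copy=False))

    return _node(hm.astype(offsets.dtype, copy=False), (offsets,), bwd)


def homography_grid(
    hmat: Tensor,
    out_hw: tuple,
    pre: np.ndarray | None = None,
    post: np.ndarray | None = None,
    invert: bool = True,
) -> Tensor:
    """Sampling grid q ↦ M·q with M = pre @ (H⁻¹ if invert else H) @ post.

    Output (N,2,H,W) pixel coordinates, differentiable w.r.t. ``hmat``.
    ``pre``/``post`` are constant 3x3 matrices used for canvas translations
    and pyramid-scale changes of coordinates.
    """
    n = hmat.shape[0]
    oh, ow = out_hw
    eye = np.eye(3)
    pre = eye if pre is None else np.asarray(pre, dtype=np.float64)
    post = eye if post is None else np.asarray(post, dtype=np.float64)
    hm = hmat.data.astype(np.float64)
    inner = np.linalg.inv(hm) if invert else hm
    m = pre[None] @ inner @ post[None]

    jj, ii = np.meshgrid(np.arange(ow, dtype=np.float64), np.arange(oh, dtype=np.float64))
    q = np.stack([jj.ravel(), ii.ravel(), np.ones(oh * ow)], axis=0)  # (3,P)
    ph = m @ q  # (N,3,P)
    wdiv = ph[:, 2]
    if np.any(np.abs(wdiv) < 1e-12):
        raise ValueError("homography sends grid points to infinity")
    gx = ph[:, 0] / wdiv
    gy = ph[:, 1] / wdiv
    grid = np.stack([gx, gy], axis=1).reshape(n, 2, oh, ow)

    def bwd(g):
        gq = g.reshape(n, 2, oh * ow).astype(np.float64)
        dgx, dgy = gq[:, 0], gq[:, 1]
        dm = np.empty((n, 3, 3))
        dm[:, 0] = ((dgx / wdiv)[:, None, :] * q[None]).sum(axis=2)
        dm[:, 1] = ((dgy / wdiv)[:, None, :] * q[None]).sum(axis=2)
        dm[:, 2] = ((-(dgx * gx + dgy * gy) / wdiv)[:, None, :] * q[None]).sum(axis=2)
        dinner = pre.T[None] @ dm @ post.T[None]
        if invert:
            it = inner.transpose(0, 2, 1)
            dh = -it @ dinner @ it
        else:
            dh = dinner
        hmat._accum(dh.astype(hmat.dtype, copy=False))

    return _node(grid.astype(hmat.dtype, copy=False), (hmat,), bwd)
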