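"""Gradient and semantics checks for the autograd engine.

Analytic gradients of every composite op are compared against central finite
differences on small float64 instances.
"""

import numpy as np
import pytest

from endostitch import nn
from endostitch.nn import ops


def _t64(a):
    return nn.Tensor(np.asarray(a, np.float64), requires_grad=True)


def gradcheck(f, xs, eps=1e-6, tol=1e-5):
    out = f(*xs)
    (out.sum() if out.size > 1 else out).backward()
    for x in xs:
        num = np.zeros_like(x.data)
        it = np.nditer(x.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x.data[i]
            x.data[i] = orig + eps
            fp = f(*xs).sum().item()
            x.data[i] = orig - eps
            fm = f(*xs).sum().item()
            x.data[i] = orig
            num[i] = (fp - fm) / (2 * eps)
        rel = np.abs(num - x.grad).max() / (np.abs(num).max() + 1e-8)
        assert rel < tol, f"gradient mismatch {rel:.2e}"
        x.zero_grad()


@pytest.mark.parametrize("stride", [1, 2])
def test_conv2d_gradients(rng, stride):
    x = _t64(rng.normal(size=(2, 3, 7, 7)))
    w = _t64(rng.normal(size=(4, 3, 3, 3)))
    b = _t64(rng.normal(size=(4,)))
    gradcheck(lambda x, w, b: ops.conv2d(x, w, b, stride=stride, pad=1), [x, w, b])


def test_conv_transpose_gradients_and_shape(rng):
    x = _t64(rng.normal(size=(2, 3, 4, 4)))
    w = _t64(rng.normal(size=(3, 2, 4, 4)))
    b = _t64(rng.normal(size=(2,)))
    assert ops.conv_transpose2d(x, w, b).shape == (2, 2, 8, 8)
    gradcheck(ops.conv_transpose2d, [x, w, b])


def test_pooling_gradients(rng):
    x = _t64(rng.normal(size=(1, 2, 6, 6)))
    gradcheck(lambda x: ops.avg_pool2d(x, 2), [x])
    gradcheck(lambda x: ops.adaptive_avg_pool2d(x, (4, 4)), [x])
    # adaptive pooling handles non-divisible inputs via fractional bins
    y = ops.adaptive_avg_pool2d(_t64(rng.normal(size=(1, 1, 7, 5))), (4, 4))
    assert y.shape == (1, 1, 4, 4)


def test_grid_sample_gradients(rng):
    x = _t64(rng.normal(size=(2, 2, 5, 5)))
    g = _t64(rng.uniform(-0.7, 4.7, size=(2, 2, 3, 3)) + 0.013)
    gradcheck(lambda x, g: ops.grid_sample(x, g), [x, g], eps=1e-7, tol=1e-4)


def test_grid_sample_zero_padding(rng):
    x = nn.Tensor(np.ones((1, 1, 4, 4)))
    g = nn.Tensor(np.full((1, 2, 1, 1), 10.0))  # far outside
    assert ops.grid_sample(x, g).data[0, 0, 0, 0] == 0.0


def test_correlation_matches_bruteforce(rng):
    a = rng.normal(size=(1, 3, 5, 5)).astype(np.float64)
    b = rng.normal(size=(1, 3, 5, 5)).astype(np.float64)
    r = 1
    out = ops.local_correlation(nn.Tensor(a), nn.Tensor(b), r).data[0]
    d = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            for yy in range(5):
                for xx in range(5):
                    y2, x2 = yy + dy, xx + dx
                    ref = 0.0
                    if 0 <= y2 < 5 and 0 <= x2 < 5:
                        ref = float((a[0, :, yy, xx] * b[0, :, y2, x2]).sum())
                    assert abs(out[d, yy, xx] - ref) < 1e-6
            d += 1


def test_correlation_normalised_features(rng):
    f = ops.l2_normalize(_t64(rng.normal(size=(1, 8, 4, 4))))
    corr = ops.local_correlation(f, f, 1)
    centre = corr.data[0, 4]  # zero-displacement channel
    assert np.allclose(centre, 1.0, atol=1e-6)
    assert corr.data.max() <= 1.0 + 1e-6


def test_softmax_and_clamp(rng):
    x = _t64(rng.normal(size=(2, 5, 3, 3)))
    w = nn.Tensor(rng.normal(size=(2, 5, 3, 3)))  # sum of raw softmax is constant
    gradcheck(lambda x: (x.softmax(axis=1) * w).sum(), [x], tol=1e-4)
    p = x.softmax(axis=1)
    assert np.allclose(p.data.sum(axis=1), 1.0)
    # straight-through clamp: values clipped, gradient passes
    y = _t64([[-50.0, 3.0, 50.0]])
    z = y.clamp_st(32.0)
    assert np.allclose(z.data, [[-32.0, 3.0, 32.0]])
    z.sum().backward()
    assert np.allclose(y.grad, 1.0)


def test_dlt_solve_reprojects_exactly(rng):
    off = rng.uniform(-20, 20, size=(3, 8))
    hs = ops.dlt_solve(nn.Tensor(off), 128).data
    s = 127.0
    base = np.array([[0, 0], [s, 0], [s, s], [0, s]])
    for n in range(3):
        for k in range(4):
            p = hs[n] @ np.array([base[k, 0], base[k, 1], 1.0])
            p = p[:2] / p[2]
            assert np.abs(p - (base[k] + off[n].reshape(4, 2)[k])).max() < 1e-8


def test_dlt_and_warp_chain_gradients(rng):
    img = _t64(rng.uniform(size=(2, 3, 16, 16)))
    off = _t64(rng.uniform(-3, 3, size=(2, 8)))

    def chain(img, off):
        h = ops.dlt_solve(off, 16)
        grid = ops.homography_grid(h, (16, 16), invert=True)
        return ops.grid_sample(img, grid).abs().mean()

    gradcheck(chain, [img, off], eps=1e-6, tol=1e-3)


def test_homography_grid_scale_matrices(rng):
    off = _t64(rng.uniform(-3, 3, size=(1, 8)))

    def chain(off):
        h = ops.dlt_solve(off, 16)
        pre = np.diag([0.5, 0.5, 1.0])
        post = np.diag([2.0, 2.0, 1.0])
        return ops.homography_grid(h, (8, 8), pre=pre, post=post, invert=False).sum()

    gradcheck(chain, [off], eps=1e-6, tol=1e-4)


def test_resize_bilinear_preserves_mean():
    x = nn.Tensor(np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4))
    y = ops.resize_bilinear(x, (8, 8))
    assert y.shape == (1, 1, 8, 8)
    assert abs(y.data.mean() - x.data.mean()) < 1e-9


def test_adam_reduces_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 0.1


def test_module_state_dict_roundtrip(rng):
    a = nn.Conv2d(3, 4, rng=rng)
    b = nn.Conv2d(3, 4, rng=np.random.default_rng(99))
    state = a.state_dict()
    b.load_state_dict(state)
    assert np.array_equal(a.weight.data, b.weight.data)
    with pytest.raises(ValueError):
        b.load_state_dict({"weight": state["weight"]})
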