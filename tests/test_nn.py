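"""The numpy autodiff engine: finite-difference checks and layer oracles."""

import numpy as np
import pytest

from blastoseg import nn
from blastoseg.nn import autodiff as ad


def _leaf(arr):
    # a non-Parameter tensor that still receives a gradient
    t = ad.Tensor(arr)
    t._backward = lambda g: None
    return t


def _numeric_grad(f, arr, eps=1e-3):
    g = np.zeros(arr.shape, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def _check(analytic, numeric, tol=2e-2):
    scale = max(np.abs(numeric).max(), 1e-6)
    assert np.abs(analytic - numeric).max() / scale < tol


class TestGradients:
    def test_grouped_strided_conv(self, rng):
        x = _leaf(rng.normal(0, 1, (2, 4, 7, 7)).astype(np.float32))
        w = ad.Parameter(rng.normal(0, 0.5, (6, 2, 3, 3)).astype(np.float32))
        b = ad.Parameter(rng.normal(0, 0.5, 6).astype(np.float32))
        proj = rng.normal(0, 1, (2, 6, 4, 4)).astype(np.float32)

        def run():
            return float((ad.conv2d(x, w, b, stride=2, padding=1, groups=2).data * proj).sum())

        out = ad.conv2d(x, w, b, stride=2, padding=1, groups=2)
        out.grad = proj.copy()
        out._backward(out.grad)
        _check(w.grad, _numeric_grad(run, w.data))
        _check(b.grad, _numeric_grad(run, b.data))
        _check(x.grad, _numeric_grad(run, x.data))

    def test_transposed_conv(self, rng):
        x = _leaf(rng.normal(0, 1, (2, 3, 5, 5)).astype(np.float32))
        w = ad.Parameter(rng.normal(0, 0.5, (3, 4, 3, 3)).astype(np.float32))
        b = ad.Parameter(rng.normal(0, 0.5, 4).astype(np.float32))
        proj = rng.normal(0, 1, (2, 4, 10, 10)).astype(np.float32)

        def run():
            return float((ad.conv_transpose2d(x, w, b).data * proj).sum())

        out = ad.conv_transpose2d(x, w, b)
        assert out.data.shape == (2, 4, 10, 10)  # exact side doubling
        out.grad = proj.copy()
        out._backward(out.grad)
        _check(w.grad, _numeric_grad(run, w.data))
        _check(x.grad, _numeric_grad(run, x.data))

    def test_batch_norm_training_mode(self, rng):
        x = _leaf(rng.normal(0, 1, (3, 4, 5, 5)).astype(np.float32))
        gamma = ad.Parameter(rng.uniform(0.5, 1.5, 4).astype(np.float32))
        beta = ad.Parameter(rng.normal(0, 0.3, 4).astype(np.float32))
        proj = rng.normal(0, 1, (3, 4, 5, 5)).astype(np.float32)

        def run():
            rm, rv = np.zeros(4, np.float32), np.ones(4, np.float32)
            return float((ad.batch_norm(x, gamma, beta, rm, rv, True).data * proj).sum())

        rm, rv = np.zeros(4, np.float32), np.ones(4, np.float32)
        out = ad.batch_norm(x, gamma, beta, rm, rv, True)
        out.grad = proj.copy()
        out._backward(out.grad)
        _check(gamma.grad, _numeric_grad(run, gamma.data))
        _check(beta.grad, _numeric_grad(run, beta.data))
        _check(x.grad, _numeric_grad(run, x.data))

    def test_softmax_dice_chain(self, rng):
        x = _leaf(rng.normal(0, 1, (2, 5, 4, 4)).astype(np.float32))
        onehot = np.zeros((2, 5, 4, 4), np.float32)
        lab = rng.integers(0, 5, (2, 4, 4))
        for c in range(5):
            onehot[:, c][lab == c] = 1

        def run():
            return float(ad.generalized_dice_loss(ad.softmax_channels(x), onehot).data)

        loss = ad.generalized_dice_loss(ad.softmax_channels(x), onehot)
        ad.backward(loss)
        _check(x.grad, _numeric_grad(run, x.data), tol=5e-2)


class TestLayers:
    def test_grouped_conv_parameter_count_closed_form(self, rng):
        # k^2 * (Cin/g) * Cout + Cout; the worked 8->8, g=4 case gives 152
        conv = nn.Conv2d(8, 8, 3, groups=4, rng=rng)
        assert conv.weight.data.size + conv.bias.data.size == 3 * 3 * (8 // 4) * 8 + 8 == 152
        plain = nn.Conv2d(4, 8, 3, rng=rng)
        assert plain.weight.data.size + plain.bias.data.size == 3 * 3 * 4 * 8 + 8 == 296
        bn = nn.BatchNorm2d(16)
        assert sum(p.data.size for p in bn.parameters()) == 2 * 16

    def test_conv_rejects_indivisible_groups(self, rng):
        with pytest.raises(ValueError):
            nn.Conv2d(6, 8, 3, groups=4, rng=rng)

    def test_paired_conv_equals_two_convs(self, rng):
        x = _leaf(rng.normal(0, 1, (2, 4, 6, 6)).astype(np.float32))
        wa = ad.Parameter(rng.normal(0, 0.5, (8, 2, 3, 3)).astype(np.float32))
        wb = ad.Parameter(rng.normal(0, 0.5, (8, 2, 3, 3)).astype(np.float32))
        ba = ad.Parameter(rng.normal(0, 0.1, 8).astype(np.float32))
        bb = ad.Parameter(rng.normal(0, 0.1, 8).astype(np.float32))
        pair = ad.conv2d_pair(x, wa, ba, wb, bb, groups=2)
        a = ad.conv2d(ad.Tensor(x.data), wa, ba, groups=2)
        b = ad.conv2d(ad.Tensor(x.data), wb, bb, groups=2)
        assert np.array_equal(pair.data, np.concatenate([a.data, b.data], axis=1))
        proj = rng.normal(0, 1, pair.data.shape).astype(np.float32)
        pair.grad = proj.copy()
        pair._backward(pair.grad)
        ga, gb = wa.grad.copy(), wb.grad.copy()
        wa.grad = wb.grad = None
        x2 = _leaf(x.data)
        a = ad.conv2d(x2, wa, ba, groups=2)
        a.grad = proj[:, :8].copy()
        a._backward(a.grad)
        b = ad.conv2d(x2, wb, bb, groups=2)
        b.grad = proj[:, 8:].copy()
        b._backward(b.grad)
        assert np.allclose(ga, wa.grad, atol=1e-5)
        assert np.allclose(gb, wb.grad, atol=1e-5)
        assert np.allclose(x.grad, x2.grad, atol=1e-5)

    def test_batch_norm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm2d(3)
        x = rng.normal(2.0, 3.0, (4, 3, 8, 8)).astype(np.float32)
        for _ in range(50):
            bn(ad.Tensor(x), training=True)
        out = bn(ad.Tensor(x), training=False).data
        assert abs(out.mean()) < 0.2 and abs(out.std() - 1.0) < 0.2

    def test_adam_decreases_quadratic(self):
        p = ad.Parameter(np.array([5.0, -3.0], dtype=np.float32), decay=False)
        opt = nn.Adam([p], lr=0.1, l2=0.0)
        for _ in range(200):
            opt.zero_grad()
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_l2_applies_only_to_decay_parameters(self):
        w = ad.Parameter(np.ones(2, dtype=np.float32), decay=True)
        b = ad.Parameter(np.ones(2, dtype=np.float32), decay=False)
        opt = nn.Adam([w, b], lr=0.01, l2=0.1)
        opt.zero_grad()
        w.grad = np.zeros(2, np.float32)
        b.grad = np.zeros(2, np.float32)
        opt.step()
        assert np.all(w.data < 1.0)  # decayed
        assert np.all(b.data == 1.0)  # untouched
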