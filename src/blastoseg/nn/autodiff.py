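"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the segmentation network needs:
2-D (grouped/strided) convolution, transposed convolution, batch
normalization, ReLU, channel concatenation, channel softmax and the
generalized Dice loss.  Tensors form a DAG; :func:`backward` walks it in
reverse topological order accumulating gradients.

All arrays are ``float32`` in NCHW layout.  Convolutions are evaluated as
windowed tensor contractions (``sliding_window_view`` + ``tensordot``) so
the heavy lifting happens in BLAS.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "backward",
    "conv2d",
    "conv_transpose2d",
    "batch_norm",
    "relu",
    "concat",
    "softmax_channels",
    "generalized_dice_loss",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def requires_grad(self) -> bool:
        return self._backward is not None or isinstance(self, Parameter)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    """A learnable leaf tensor.

    ``decay`` marks whether L2 regularization applies (convolution kernels
    only; biases and batch-norm scale/shift are exempt).
    """

    __slots__ = ("decay", "name")

    def __init__(self, data: np.ndarray, decay: bool = False, name: str = ""):
        super().__init__(data)
        self.decay = decay
        self.name = name


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the graph."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def _needs(t: Tensor) -> bool:
    return isinstance(t, Parameter) or t._backward is not None


# ---------------------------------------------------------------------------
# convolution


def _pointwise(x: Tensor, w: Parameter, b: Parameter | None) -> Tensor:
    """1x1 stride-1 ungrouped convolution as a batched matmul."""
    xd = x.data
    n, cin, h, wdt = xd.shape
    cout = w.data.shape[0]
    w2 = w.data.reshape(cout, cin)
    xm = xd.reshape(n, cin, h * wdt)
    out = np.matmul(w2, xm)  # (n, cout, h*w)
    if b is not None:
        out += b.data.reshape(1, -1, 1)

    def bwd(go: np.ndarray) -> None:
        gom = go.reshape(n, cout, h * wdt)
        if b is not None:
            b._accumulate(gom.sum(axis=(0, 2)))
        gw = np.matmul(gom, xm.transpose(0, 2, 1)).sum(axis=0)
        if w.grad is None:
            w.grad = np.zeros_like(w.data)
        w.grad += gw.reshape(w.data.shape)
        if _needs(x):
            x._accumulate(np.matmul(w2.T, gom).reshape(xd.shape))

    return Tensor(
        out.reshape(n, cout, h, wdt),
        parents=(x, w) + (() if b is None else (b,)),
        backward_fn=bwd,
    )


def conv2d(
    x: Tensor,
    w: Parameter,
    b: Parameter | None,
    stride: int = 1,
    padding: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D cross-correlation. ``w`` has shape (Cout, Cin/g, kh, kw)."""
    xd, wd = x.data, w.data
    n, cin, h, wdt = xd.shape
    cout, cg, kh, kw = wd.shape
    g = groups
    if cin % g or cout % g or cin // g != cg:
        raise ValueError(
            f"channels ({cin}->{cout}) not divisible into {g} groups of width {cg}"
        )
    if kh == 1 and kw == 1 and stride == 1 and g == 1:
        return _pointwise(x, w, b)
    cog = cout // g
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than (padded) input")
    xp = (
        np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else xd
    )
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.empty((n, cout, ho, wo), dtype=np.float32)
    cols: list[np.ndarray] = []  # cached im2col matrices, one per group
    for gi in range(g):
        wg2 = wd[gi * cog : (gi + 1) * cog].reshape(cog, cg * kh * kw)
        colg = np.ascontiguousarray(
            win[:, gi * cg : (gi + 1) * cg].transpose(0, 2, 3, 1, 4, 5)
        ).reshape(n * ho * wo, cg * kh * kw)
        cols.append(colg)
        out[:, gi * cog : (gi + 1) * cog] = (
            (colg @ wg2.T).reshape(n, ho, wo, cog).transpose(0, 3, 1, 2)
        )
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def bwd(go: np.ndarray) -> None:
        if b is not None:
            b._accumulate(go.sum(axis=(0, 2, 3)))
        need_x = _needs(x)
        # channels-last scratch so the strided scatter-adds touch contiguous memory
        gxp = np.zeros((n, h + 2 * padding, wdt + 2 * padding, cin), dtype=np.float32) if need_x else None
        if w.grad is None:
            w.grad = np.zeros_like(wd)
        for gi in range(g):
            gog = np.ascontiguousarray(
                go[:, gi * cog : (gi + 1) * cog].transpose(0, 2, 3, 1)
            ).reshape(n * ho * wo, cog)
            wg2 = wd[gi * cog : (gi + 1) * cog].reshape(cog, cg * kh * kw)
            w.grad[gi * cog : (gi + 1) * cog] += (gog.T @ cols[gi]).reshape(cog, cg, kh, kw)
            if need_x:
                gcol = (gog @ wg2).reshape(n, ho, wo, cg, kh, kw)
                for ki in range(kh):
                    for kj in range(kw):
                        gxp[
                            :,
                            ki : ki + stride * ho : stride,
                            kj : kj + stride * wo : stride,
                            gi * cg : (gi + 1) * cg,
                        ] += gcol[..., ki, kj]
        if need_x:
            gx = gxp.transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding : padding + h, padding : padding + wdt]
            x._accumulate(np.ascontiguousarray(gx))

    return Tensor(out, parents=(x, w) + (() if b is None else (b,)), backward_fn=bwd)


def conv2d_pair(
    x: Tensor,
    w_a: Parameter,
    b_a: Parameter | None,
    w_b: Parameter,
    b_b: Parameter | None,
    stride: int = 1,
    padding: int = 1,
    groups: int = 1,
) -> Tensor:
    """Two same-shaped grouped convolutions of the same input, fused.

    Returns their channel concatenation (path A first).  Mathematically
    identical to two :func:`conv2d` calls + :func:`concat`, but shares the
    im2col expansion between the paths — the dual-path grouped block's
    hot path.
    """
    xd = x.data
    wd_a, wd_b = w_a.data, w_b.data
    if wd_a.shape != wd_b.shape:
        raise ValueError("paired convolution paths must share a weight shape")
    n, cin, h, wdt = xd.shape
    cout, cg, kh, kw = wd_a.shape
    g = groups
    if cin % g or cout % g or cin // g != cg:
        raise ValueError(f"channels ({cin}->{cout}) not divisible into {g} groups")
    cog = cout // g
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    xp = (
        np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else xd
    )
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.empty((n, 2 * cout, ho, wo), dtype=np.float32)
    cols: list[np.ndarray] = []
    for gi in range(g):
        sl = slice(gi * cog, (gi + 1) * cog)
        wg2 = np.concatenate(
            [wd_a[sl].reshape(cog, -1), wd_b[sl].reshape(cog, -1)], axis=0
        )
        colg = np.ascontiguousarray(
            win[:, gi * cg : (gi + 1) * cg].transpose(0, 2, 3, 1, 4, 5)
        ).reshape(n * ho * wo, cg * kh * kw)
        cols.append(colg)
        og = (colg @ wg2.T).reshape(n, ho, wo, 2 * cog).transpose(0, 3, 1, 2)
        out[:, sl] = og[:, :cog]
        out[:, cout + gi * cog : cout + (gi + 1) * cog] = og[:, cog:]
    if b_a is not None:
        out[:, :cout] += b_a.data.reshape(1, -1, 1, 1)
        out[:, cout:] += b_b.data.reshape(1, -1, 1, 1)

    def bwd(go: np.ndarray) -> None:
        if b_a is not None:
            b_a._accumulate(go[:, :cout].sum(axis=(0, 2, 3)))
            b_b._accumulate(go[:, cout:].sum(axis=(0, 2, 3)))
        need_x = _needs(x)
        gxp = (
            np.zeros((n, h + 2 * padding, wdt + 2 * padding, cin), dtype=np.float32)
            if need_x
            else None
        )
        for wp in (w_a, w_b):
            if wp.grad is None:
                wp.grad = np.zeros_like(wp.data)
        for gi in range(g):
            sl = slice(gi * cog, (gi + 1) * cog)
            gog = np.ascontiguousarray(
                np.concatenate(
                    [go[:, sl], go[:, cout + gi * cog : cout + (gi + 1) * cog]], axis=1
                ).transpose(0, 2, 3, 1)
            ).reshape(n * ho * wo, 2 * cog)
            gw = (gog.T @ cols[gi]).reshape(2 * cog, cg, kh, kw)
            w_a.grad[sl] += gw[:cog]
            w_b.grad[sl] += gw[cog:]
            if need_x:
                wg2 = np.concatenate(
                    [wd_a[sl].reshape(cog, -1), wd_b[sl].reshape(cog, -1)], axis=0
                )
                gcol = (gog @ wg2).reshape(n, ho, wo, cg, kh, kw)
                for ki in range(kh):
                    for kj in range(kw):
                        gxp[
                            :,
                            ki : ki + stride * ho : stride,
                            kj : kj + stride * wo : stride,
                            gi * cg : (gi + 1) * cg,
                        ] += gcol[..., ki, kj]
        if need_x:
            gx = gxp.transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding : padding + h, padding : padding + wdt]
            x._accumulate(np.ascontiguousarray(gx))

    parents = [x, w_a, w_b] + [p for p in (b_a, b_b) if p is not None]
    return Tensor(out, parents=tuple(parents), backward_fn=bwd)


def conv_transpose2d(
    x: Tensor,
    w: Parameter,
    b: Parameter | None,
    stride: int = 2,
    padding: int = 1,
    output_padding: int = 1,
) -> Tensor:
    """Transposed 2-D convolution. ``w`` has shape (Cin, Cout, kh, kw)."""
    xd, wd = x.data, w.data
    n, cin, h, wdt = xd.shape
    cin_w, cout, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"input channels {cin} != weight channels {cin_w}")
    ho = (h - 1) * stride - 2 * padding + kh + output_padding
    wo = (wdt - 1) * stride - 2 * padding + kw + output_padding
    fh, fw = (h - 1) * stride + kh, (wdt - 1) * stride + kw
    # (n, h, w, cout, kh, kw): every input pixel's stamped kernel contribution
    t = np.tensordot(xd, wd, axes=([1], [0]))
    full = np.zeros((n, cout, fh, fw), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            full[:, :, ki : ki + stride * h : stride, kj : kj + stride * wdt : stride] += (
                t[..., ki, kj].transpose(0, 3, 1, 2)
            )
    out = full[:, :, padding : padding + ho, padding : padding + wo]
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def bwd(go: np.ndarray) -> None:
        if b is not None:
            b._accumulate(go.sum(axis=(0, 2, 3)))
        gfull = np.zeros((n, cout, fh, fw), dtype=np.float32)
        gfull[:, :, padding : padding + ho, padding : padding + wo] = go
        gwin = sliding_window_view(gfull, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # gwin: (n, cout, h, w, kh, kw)
        if w.grad is None:
            w.grad = np.zeros_like(wd)
        w.grad += np.tensordot(xd, gwin, axes=([0, 2, 3], [0, 2, 3]))
        if _needs(x):
            gx = np.tensordot(gwin, wd, axes=([1, 4, 5], [1, 2, 3]))  # (n, h, w, cin)
            x._accumulate(gx.transpose(0, 3, 1, 2))

    return Tensor(
        np.ascontiguousarray(out),
        parents=(x, w) + (() if b is None else (b,)),
        backward_fn=bwd,
    )


# ---------------------------------------------------------------------------
# normalization / activation / structure


def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    use_batch_stats: bool | None = None,
) -> Tensor:
    xd = x.data
    if use_batch_stats is None:
        use_batch_stats = training
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean += momentum * (mean - running_mean)
        running_var += momentum * (var - running_var)
        mean_b = mean.reshape(1, -1, 1, 1)
        inv_std_b = (1.0 / np.sqrt(var + eps)).reshape(1, -1, 1, 1)
    elif use_batch_stats:
        # instance statistics: per sample, per channel -> batch independent
        mean_b = xd.mean(axis=(2, 3), keepdims=True)
        inv_std_b = 1.0 / np.sqrt(xd.var(axis=(2, 3), keepdims=True) + eps)
    else:
        mean_b = running_mean.reshape(1, -1, 1, 1)
        inv_std_b = (1.0 / np.sqrt(running_var + eps)).reshape(1, -1, 1, 1)
    xhat = (xd - mean_b) * inv_std_b
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bwd(go: np.ndarray) -> None:
        gamma._accumulate((go * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(go.sum(axis=(0, 2, 3)))
        if not _needs(x):
            return
        gs = gamma.data.reshape(1, -1, 1, 1) * inv_std_b
        if training:
            mean_go = go.mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            mean_goxh = (go * xhat).mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            x._accumulate(gs * (go - mean_go - xhat * mean_goxh))
        else:
            x._accumulate(gs * go)

    return Tensor(out, parents=(x, gamma, beta), backward_fn=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(go: np.ndarray) -> None:
        if _needs(x):
            x._accumulate(go * mask)

    return Tensor(out, parents=(x,), backward_fn=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(go: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs(t):
                sl = [slice(None)] * go.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(go[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bwd(go: np.ndarray) -> None:
        if _needs(x):
            dot = (go * p).sum(axis=1, keepdims=True)
            x._accumulate(p * (go - dot))

    return Tensor(p, parents=(x,), backward_fn=bwd)


def generalized_dice_loss(probs: Tensor, one_hot: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Class-volume weighted Dice loss, ``w_c = 1 / (sum_i g_ci)^2``.

    ``loss = 1 - (2 * sum_c w_c sum_i p g + eps) / (sum_c w_c sum_i (p + g) + eps)``
    computed over the whole batch.  A class absent from the batch has an
    infinite nominal weight; it is excluded (w_c = 0) so that it cannot
    dominate the loss, with epsilon guarding the resulting ratios.
    """
    p = probs.data
    g = one_hot.astype(np.float32)
    if p.shape != g.shape:
        raise ValueError(f"probabilities {p.shape} vs targets {g.shape}")
    vol = g.sum(axis=(0, 2, 3))
    with np.errstate(divide="ignore"):
        wc = np.where(vol > 0, 1.0 / np.maximum(vol, 1.0) ** 2, 0.0)
    inter = (p * g).sum(axis=(0, 2, 3))
    total = (p + g).sum(axis=(0, 2, 3))
    num = 2.0 * float((wc * inter).sum()) + eps
    den = float((wc * total).sum()) + eps
    loss = 1.0 - num / den

    def bwd(go: np.ndarray) -> None:
        if _needs(probs):
            # d loss / d p_ci = -(2 w_c g_ci * den - num * w_c) / den^2
            wcb = wc.reshape(1, -1, 1, 1)
            gp = -(2.0 * wcb * g * den - num * wcb) / den**2
            probs._accumulate(go * gp)

    return Tensor(np.float32(loss), parents=(probs,), backward_fn=bwd)
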