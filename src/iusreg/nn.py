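"""Minimal reverse-mode autodiff over numpy for small 3D conv-nets.

Everything here operates on float32 arrays in channels-last layout
(N, D, H, W, C) — with the channel axis contiguous, the im2col gather for
convolution reduces to long memcpy runs, which is what makes a pure-numpy
3D conv-net trainable on a CPU. The operation set is exactly what a 3D
U-Net needs: same-padding 3x3x3 convolution, 2x max-pooling, 2x transposed
convolution, instance normalization, ReLU, sigmoid, channel concatenation,
dropout, and a soft Tversky loss. Gradients are accumulated by topological
traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv3d", "conv3d_1x1", "conv_transpose3d",
           "maxpool3d", "instance_norm", "relu", "sigmoid",
           "concat_channels", "dropout", "tversky_loss_op", "sgd_step"]

F32 = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=F32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(F32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _offsets3():
    for i in (0, 1, 2):
        for j in (0, 1, 2):
            for k in (0, 1, 2):
                yield i, j, k


def conv3d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Same-padding 3x3x3 convolution; w has shape (27, C, O).

    Computed as 27 pointwise GEMMs followed by shifted accumulation into a
    padded output buffer — every memory move is a contiguous run, which is
    the whole performance story for small channel counts.
    """
    N, D, H, W, C = x.shape
    O = w.data.shape[2]
    x2 = x.data.reshape(N * D * H * W, C)
    outp = np.zeros((N, D + 2, H + 2, W + 2, O), dtype=F32)
    for idx, (i, j, k) in enumerate(_offsets3()):
        y = (x2 @ w.data[idx]).reshape(N, D, H, W, O)
        # x[q] contributes to out[q + 1 - offset]
        outp[:, 2 - i:2 - i + D, 2 - j:2 - j + H, 2 - k:2 - k + W, :] += y
    out = outp[:, 1:-1, 1:-1, 1:-1, :] + b.data

    def backward(g):
        gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2, 3)))
        need_w = w.requires_grad
        need_x = x.requires_grad
        dw = np.empty_like(w.data) if need_w else None
        dx2 = np.zeros((N * D * H * W, C), dtype=F32) if need_x else None
        for idx, (i, j, k) in enumerate(_offsets3()):
            gk = np.ascontiguousarray(
                gp[:, 2 - i:2 - i + D, 2 - j:2 - j + H,
                   2 - k:2 - k + W, :]).reshape(-1, O)
            if need_w:
                dw[idx] = x2.T @ gk
            if need_x:
                dx2 += gk @ w.data[idx].T
        if need_w:
            w._accumulate(dw)
        if need_x:
            x._accumulate(dx2.reshape(x.shape))

    return Tensor(np.ascontiguousarray(out), (x, w, b), backward)


def conv3d_1x1(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Pointwise convolution; w has shape (C, O)."""
    out = x.data @ w.data + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.tensordot(x.data, g, axes=([0, 1, 2, 3],
                                                        [0, 1, 2, 3])))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return Tensor(out, (x, w, b), backward)


def conv_transpose3d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """2x2x2 stride-2 up-convolution; w has shape (C, 8*O)."""
    N, D, H, W, C = x.shape
    O = w.data.shape[1] // 8
    xm = x.data.reshape(N * D * H * W, C)
    prod = (xm @ w.data).reshape(N, D, H, W, 8, O)
    out = np.empty((N, 2 * D, 2 * H, 2 * W, O), dtype=F32)
    for idx, (i, j, k) in enumerate(
            ((i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1))):
        out[:, i::2, j::2, k::2, :] = prod[:, :, :, :, idx, :]
    out += b.data

    def backward(g):
        gsub = np.empty((N, D, H, W, 8, O), dtype=F32)
        for idx, (i, j, k) in enumerate(
                ((i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1))):
            gsub[:, :, :, :, idx, :] = g[:, i::2, j::2, k::2, :]
        gm = gsub.reshape(N * D * H * W, 8 * O)
        if w.requires_grad:
            w._accumulate(xm.T @ gm)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            x._accumulate((gm @ w.data.T).reshape(x.shape))

    return Tensor(out, (x, w, b), backward)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 stride-2 max pooling; spatial dims must be even."""
    N, D, H, W, C = x.shape
    assert D % 2 == 0 and H % 2 == 0 and W % 2 == 0, "odd spatial dims"
    xr = x.data.reshape(N, D // 2, 2, H // 2, 2, W // 2, 2, C)
    xf = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 7, 2, 4, 6)) \
        .reshape(N, D // 2, H // 2, W // 2, C, 8)
    arg = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxf = np.zeros_like(xf)
        np.put_along_axis(dxf, arg[..., None], g[..., None], axis=-1)
        dx = dxf.reshape(N, D // 2, H // 2, W // 2, C, 2, 2, 2).transpose(
            0, 1, 5, 2, 6, 3, 7, 4).reshape(N, D, H, W, C)
        x._accumulate(np.ascontiguousarray(dx))

    return Tensor(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Parameter, beta: Parameter,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = (1.0 / np.sqrt(var + eps)).astype(F32)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=ax, keepdims=True)
            m2 = (gy * xhat).mean(axis=ax, keepdims=True)
            x._accumulate(inv * (gy - m1 - xhat * m2))

    return Tensor(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[-1]
    out = np.concatenate([a.data, b.data], axis=-1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[..., :ca])
        if b.requires_grad:
            b._accumulate(g[..., ca:])

    return Tensor(out, (a, b), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(F32) / F32(1.0 - p)
    out = x.data * keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor(out, (x,), backward)


def tversky_loss_op(probs: Tensor, target: np.ndarray, alpha: float,
                    beta: float, smooth: float = 1e-5) -> Tensor:
    """Soft Tversky loss 1 - (TP+s) / (TP + a*FP + b*FN + s) as a graph op."""
    t = np.asarray(target, dtype=F32)
    p = probs.data
    tp = float((p * t).sum(dtype=np.float64))
    fp = float((p * (1.0 - t)).sum(dtype=np.float64))
    fn = float(((1.0 - p) * t).sum(dtype=np.float64))
    num = tp + smooth
    den = tp + alpha * fp + beta * fn + smooth
    loss = 1.0 - num / den

    def backward(g):
        if probs.requires_grad:
            # d loss/d p = -(t*den - num*(t + a(1-t) - b t)) / den^2
            dnum = t
            dden = t + alpha * (1.0 - t) - beta * t
            probs._accumulate(g * (-(dnum * den - num * dden) / den ** 2))

    return Tensor(np.array(loss, dtype=F32), (probs,), backward)


def sgd_step(params, lr: float, momentum: float, state: dict):
    """In-place SGD with classical momentum; clears gradients."""
    for i, p in enumerate(params):
        if p.grad is None:
            continue
        buf = state.get(i)
        if buf is None:
            buf = np.zeros_like(p.data)
        buf = momentum * buf + p.grad
        state[i] = buf
        p.data -= F32(lr) * buf
        p.grad = None
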