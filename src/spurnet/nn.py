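"""Minimal numpy CNN engine: reverse-mode autodiff over NCHW arrays.

Provides exactly the operations the segmentation network needs — 2-D
convolution (im2col), batch normalization, ReLU, inverted dropout, 2x
bilinear upsampling, channel concatenation, elementwise addition and a
pixelwise softmax cross-entropy loss — plus an Adam optimizer. Everything
is float32/float64 numpy; there is no GPU path and no general broadcasting:
each op implements its own backward rule and the graph is unwound in
reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "batch_norm",
    "relu",
    "dropout",
    "upsample_bilinear2x",
    "concat",
    "add",
    "softmax_cross_entropy",
    "Adam",
]


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Accumulate gradients into every reachable Parameter."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here are ~100 nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._parents:
                node.grad = None  # free intermediate grads eagerly

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# convolution


def _im2col(x, k, stride, pad):
    """(N,C,H,W) -> (N, L, C*k*k) patch matrix, L = Ho*Wo."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,k,k)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    """Adjoint of _im2col: scatter patch gradients back onto the image."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dpatch = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dpatch[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride=1, pad=0):
    """2-D convolution (cross-correlation). weight: (Cout, Cin, k, k)."""
    cout, cin, k, _ = weight.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T  # (N, L, Cout)
    if bias is not None:
        out = out + bias.data
    n = x.data.shape[0]
    outc = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N, L, Cout)
        if weight.requires_grad:
            dw = np.einsum("nlc,nlk->ck", gmat, cols).reshape(weight.shape)
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = gmat @ wmat  # (N, L, Cin*k*k)
            x._accumulate(_col2im(dcols, x.data.shape, k, stride, pad, ho, wo))

    return Tensor(outc, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# normalization / activations


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running, training, momentum=0.1, eps=1e-5):
    """Per-channel batch norm over (N,H,W). `running` is a dict holding
    'mean' and 'var' buffers updated in training mode."""
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gam_inv = (gamma.data * invstd)[None, :, None, None]
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = gam_inv / m * (m * g - sum_g - xhat * sum_gx)
            else:
                dx = gam_inv * g
            x._accumulate(dx)

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def relu(x: Tensor):
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# resampling / shape ops


def _bilinear_indices(n_out, n_in):
    # align_corners=False convention: output center maps to (o+0.5)/scale-0.5
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = np.clip(src - i0, 0.0, 1.0)
    return i0, i1, w1


def upsample_bilinear2x(x: Tensor):
    """Double spatial resolution with bilinear interpolation."""
    n, c, h, w = x.data.shape
    y0, y1, wy = _bilinear_indices(2 * h, h)
    x0, x1, wx = _bilinear_indices(2 * w, w)
    wy_ = wy[None, None, :, None]
    wx_ = wx[None, None, None, :]

    rows = x.data[:, :, y0, :] * (1 - wy_) + x.data[:, :, y1, :] * wy_
    out = rows[:, :, :, x0] * (1 - wx_) + rows[:, :, :, x1] * wx_

    def backward(g):
        if not x.requires_grad:
            return
        drows = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), x0), g * (1 - wx_))
        np.add.at(drows, (slice(None), slice(None), slice(None), x1), g * wx_)
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), y0, slice(None)), drows * (1 - wy_))
        np.add.at(dx, (slice(None), slice(None), y1, slice(None)), drows * wy_)
        x._accumulate(dx)

    return Tensor(out, parents=(x,), backward=backward)


def concat(a: Tensor, b: Tensor):
    """Concatenate along the channel axis."""
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return Tensor(out, parents=(a, b), backward=backward)


def add(a: Tensor, b: Tensor):
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(out, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# loss


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean pixelwise cross-entropy. logits (N,C,H,W), labels int (N,H,W)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, c, h, w = p.shape
    idx = (
        np.repeat(np.arange(n), h * w),
        labels.reshape(-1),
        np.tile(np.repeat(np.arange(h), w), n),
        np.tile(np.arange(w), n * h),
    )
    npix = n * h * w
    loss = -np.log(np.maximum(p[idx], 1e-12)).sum() / npix

    def backward(g):
        if logits.requires_grad:
            dz = p.copy()
            onehot = np.zeros_like(dz)
            onehot[idx] = 1.0
            logits._accumulate(g * (dz - onehot) / npix)

    return Tensor(np.float64(loss), parents=(logits,), backward=backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam; the learning rate may change every step."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr=None):
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
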