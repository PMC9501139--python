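"""Minimal reverse-mode autodiff on numpy arrays for the segmentation net.

Implements exactly the operator set the network needs — 2-D convolution
(im2col), batch normalization, ReLU/sigmoid, 2x2 max pooling, nearest
upsampling, channel concatenation, global average pooling, dropout,
broadcasting add/multiply, and a weighted softmax cross-entropy — together
with an Adam optimizer.  Tensors are NCHW float64/float32 numpy arrays;
gradients are accumulated by topological backward traversal.

Every operator's backward pass is covered by finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A value in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach grad.shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    track = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=parents if track else (), backward=backward if track else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accumulate(x, g * mask)

    return _make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        _accumulate(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def tsum(x: Tensor) -> Tensor:
    """Sum all elements to a scalar."""

    def backward(g):
        _accumulate(x, np.broadcast_to(g, x.data.shape).copy())

    return _make(np.array(x.data.sum()), (x,), backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        _accumulate(a, ga)
        _accumulate(b, gb)

    return _make(np.concatenate([a.data, b.data], axis=axis), (a, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW input, OIHW weights, via im2col."""
    n, c, h, wd = x.data.shape
    oc, ic, kh, kw = w.data.shape
    assert ic == c, "channel mismatch"
    s, p = stride, padding
    oh = (h + 2 * p - kh) // s + 1
    ow = (wd + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.data.dtype)
    for di in range(kh):
        for dj in range(kw):
            cols[:, :, di, dj] = xp[:, :, di:di + s * oh:s, dj:dj + s * ow:s]
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    w2 = w.data.reshape(oc, c * kh * kw)
    out = np.matmul(w2[None], cols2).reshape(n, oc, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, oc, 1, 1)

    def backward(g):
        g2 = g.reshape(n, oc, oh * ow)
        gw = np.einsum("nop,nfp->of", g2, cols2).reshape(w.data.shape)
        _accumulate(w, gw)
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        gcols = np.matmul(w2.T[None], g2).reshape(n, c, kh, kw, oh, ow)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                gxp[:, :, di:di + s * oh:s, dj:dj + s * ow:s] += gcols[:, :, di, dj]
        gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
        _accumulate(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial size"
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accumulate(x, gx.reshape(n, c, h, w))

    return _make(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        _accumulate(x, gx)

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial dims, keepdims -> (N, C, 1, 1)."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(out, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(g):
        _accumulate(x, g * mask)

    return _make(x.data * mask, (x,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accumulate(beta, g.sum(axis=(0, 2, 3)))
        gs = gamma.data[None, :, None, None] / std[None, :, None, None]
        if training:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            gmean = g.mean(axis=(0, 2, 3), keepdims=True)
            gxhat_mean = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            _accumulate(x, gs * (g - gmean - xhat * gxhat_mean))
        else:
            _accumulate(x, gs * g)

    return _make(out, (x, gamma, beta), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          weights: np.ndarray | None = None) -> Tensor:
    """Weighted pixel-wise cross entropy, E = -sum w(x) log p(x), averaged
    over pixels; p is the softmax probability of the true class."""
    n, c, h, w = logits.data.shape
    labels = np.asarray(labels)
    if labels.max(initial=0) >= c:
        raise ValueError(
            f"class index {int(labels.max())} out of range for {c} channels"
        )
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    logp_true = z[idx_n, labels, idx_h, idx_w] - np.log(ez.sum(axis=1))[idx_n, idx_h, idx_w]
    wmap = np.ones((n, h, w)) if weights is None else np.broadcast_to(weights, (n, h, w))
    npix = n * h * w
    loss = -(wmap * logp_true).sum() / npix

    def backward(g):
        onehot = np.zeros_like(probs)
        onehot[idx_n, labels, idx_h, idx_w] = 1.0
        _accumulate(
            logits, g * (probs - onehot) * wmap[:, None, :, :] / npix
        )

    return _make(np.array(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# layers and optimizer


class Param(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Conv2d:
    """Convolution layer with He-normal init."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)))
        self.b = Param(np.zeros(cout))
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self.cin, self.cout = cin, cout

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm2d:
    def __init__(self, channels: int):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, training)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Adam:
    """Adaptive-moment optimizer."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
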