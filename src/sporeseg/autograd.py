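"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the attention-gated UNet:
2D convolution (im2col), 2x2 max pooling, bilinear 2x upsampling, batch
normalization, channel concatenation, broadcast add/multiply, ReLU,
sigmoid, global average pooling and the training losses.  Feature maps
use the NCHW layout.  All operators preserve the input dtype, so
float64 can be used for finite-difference gradient checks while
training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "max_pool2x2",
    "upsample_bilinear2x",
    "concat_channels",
    "global_avg_pool",
    "batch_norm2d",
    "relu",
    "sigmoid",
    "bce_with_logits",
    "soft_dice_loss",
]


class Tensor:
    """An array node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph-building arithmetic ------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# -- convolution ------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """im2col with columns laid out (C*k*k, N*OH*OW).

    Built from k*k slice copies whose innermost contiguous runs are full
    image rows, which keeps the copies near memory bandwidth; the
    flattened (c, i, j) order matches ``w.reshape(O, C*k*k)``.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = np.empty((k * k, c, n, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[i * k + j] = x[:, :, i : i + stride * oh : stride,
                                j : j + stride * ow : stride].transpose(1, 0, 2, 3)
    return cols.reshape(k * k * c, n * oh * ow), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` (scatter-add back to NCHW)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    dxp = np.zeros((c, n, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(k * k, c, n, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride,
                j : j + stride * ow : stride] += d[i * k + j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(dxp.transpose(1, 0, 2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation): x (N,C,H,W), w (O,C,k,k), b (O,)."""
    n, c, h, hw = x.shape
    o, ci, k, k2 = w.shape
    if ci != c or k != k2:
        raise ValueError(f"kernel {w.shape} incompatible with input {x.shape}")
    cols, oh, ow = _im2col(x.data, k, stride, pad)
    # column order is (i, j, c); reorder the kernel to match
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0).reshape(k * k * c, o).T)
    out = wmat @ cols  # (O, N*OH*OW)
    if b is not None:
        out = out + b.data[:, None]
    out_data = np.ascontiguousarray(
        out.reshape(o, n, oh, ow).transpose(1, 0, 2, 3)
    )

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, n * oh * ow)
        if w.requires_grad or w._parents:
            dw = (gmat @ cols.T).reshape(o, k, k, c).transpose(0, 3, 1, 2)
            w._accumulate(np.ascontiguousarray(dw))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(gmat.sum(axis=1))
        if x.requires_grad or x._parents:
            dcols = wmat.T @ gmat
            x._accumulate(_col2im(dcols, x.data.shape, k, stride, pad))

    return _make(out_data, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(n, c, h, w))

    return _make(out_data, (x,), backward)


_UPSAMPLE_CACHE: dict[tuple[int, str], np.ndarray] = {}


def _upsample_matrix(n_in: int, dtype) -> np.ndarray:
    """Dense (2*n_in, n_in) interpolation matrix for 2x bilinear
    upsampling of one axis (half-pixel centre convention, edge clamp)."""
    key = (n_in, np.dtype(dtype).str)
    mat = _UPSAMPLE_CACHE.get(key)
    if mat is None:
        src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
        f = np.floor(src)
        w1 = src - f
        i0 = np.clip(f, 0, n_in - 1).astype(np.intp)
        i1 = np.clip(f + 1, 0, n_in - 1).astype(np.intp)
        mat = np.zeros((2 * n_in, n_in), dtype=dtype)
        rows = np.arange(2 * n_in)
        np.add.at(mat, (rows, i0), (1.0 - w1).astype(dtype))
        np.add.at(mat, (rows, i1), w1.astype(dtype))
        _UPSAMPLE_CACHE[key] = mat
    return mat


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double both spatial dimensions by bilinear interpolation,
    expressed as two small matrix products (U_h @ x @ U_w^T)."""
    n, c, h, w = x.shape
    uh = _upsample_matrix(h, x.dtype)
    uw = _upsample_matrix(w, x.dtype)
    out_data = np.matmul(np.matmul(uh, x.data), uw.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(uh.T, g), uw))

    return _make(out_data, (x,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.shape[1] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad or t._parents:
                t._accumulate(g[:, start : start + s])
            start += s

    return _make(out_data, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keeping shape (N, C, 1, 1)."""
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(out_data, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place
    when training."""
    n, c, h, w = x.shape
    gm = gamma.data.reshape(1, c, 1, 1)
    bt = beta.data.reshape(1, c, 1, 1)
    if training:
        m = n * h * w
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.ravel()
        running_var *= 1.0 - momentum
        running_var += momentum * var.ravel()
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv_std
        out_data = gm * xhat + bt

        def backward(g):
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad or beta._parents:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                dxhat = g * gm
                dx = (
                    dxhat
                    - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) * inv_std
                x._accumulate(dx)

    else:
        inv_std = 1.0 / np.sqrt(running_var.reshape(1, c, 1, 1) + eps)
        xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * inv_std
        out_data = gm * xhat + bt

        def backward(g):
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad or beta._parents:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                x._accumulate(g * gm * inv_std)

    return _make(out_data.astype(x.dtype, copy=False), (x, gamma, beta), backward)


# -- losses -----------------------------------------------------------

def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    z = logits.data
    y = np.asarray(target, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(loss.mean(), dtype=z.dtype)

    def backward(g):
        logits._accumulate(g * (_sigmoid(z) - y) / z.size)

    return _make(out_data, (logits,), backward)


def soft_dice_loss(logits: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice coefficient of sigmoid(logits) against a binary target."""
    z = logits.data
    y = np.asarray(target, dtype=z.dtype)
    p = _sigmoid(z)
    inter = (p * y).sum()
    denom = p.sum() + y.sum() + smooth
    dice = (2.0 * inter + smooth) / denom
    out_data = np.asarray(1.0 - dice, dtype=z.dtype)

    def backward(g):
        # d(1-dice)/dp, then chain through the sigmoid
        dp = -(2.0 * y * denom - (2.0 * inter + smooth)) / denom**2
        logits._accumulate(g * dp * p * (1.0 - p))

    return _make(out_data, (logits,), backward)
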