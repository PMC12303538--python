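"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's networks are small (a few hundred thousand parameters) and run
on CPU, so a compact tape-based engine is sufficient: each operation records
its parents and a closure that accumulates gradients into them.  Convolution
is implemented with im2col + matmul; its backward pass scatters gradients
back with a 9-iteration col2im loop.  Every primitive's backward is checked
against central finite differences in the test suite.

Arrays follow the NCHW layout.  The engine is deliberately eager and
single-threaded-friendly; no broadcasting rules beyond what each primitive
states.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "conv2d",
    "instance_norm",
    "upsample_nearest2x",
    "concat_channels",
    "narrow_channels",
    "global_avg_pool2d",
    "linear",
    "batched_pointwise_conv",
    "gather_channel",
    "bce_with_logits",
    "soft_dice_loss",
    "add",
]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of two tensors of identical shape (residual joins)."""
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data + b.data
    if not _needs_grad(a, b):
        return Tensor(out_data)

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def _logistic(z: np.ndarray) -> np.ndarray:
    """Stable elementwise logistic, evaluated branch-by-branch."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    out_data = _logistic(x.data)
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    cols = view.reshape(n, c * kh * kw, ho * wo)  # copies
    return cols, (hp, wp, ho, wo)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, square stride/padding."""
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    cols, (hp, wp, ho, wo) = _im2col(x.data, kh, kw, stride, padding)
    wm = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wm, cols)  # (n, cout, ho*wo)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1)
    out_data = out.reshape(n, cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _needs_grad(*parents):
        return Tensor(out_data)

    def backward(g):
        g2 = g.reshape(n, cout, ho * wo)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(g2.sum(axis=(0, 2)))
        if weight.requires_grad or weight._parents:
            dw = np.einsum("nol,nkl->ok", g2, cols, optimize=True)
            weight._accumulate(dw.reshape(weight.shape))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wm.T, g2)  # (n, cin*kh*kw, ho*wo)
            dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
            dxp = np.zeros((n, cin, hp, wp), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + w]
            x._accumulate(dxp)

    return Tensor(out_data, parents=parents, backward=backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization with affine parameters.

    Chosen over batch statistics because partial-label batches mix classes
    and domains at batch size 4.
    """
    n, c, h, w = x.shape
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    parents = (x, gamma, beta)
    if not _needs_grad(*parents):
        return Tensor(out_data)

    def backward(g):
        if beta.requires_grad or beta._parents:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            m = h * w
            gx = g * gamma.data.reshape(1, c, 1, 1)
            t1 = gx.sum(axis=(2, 3), keepdims=True) / m
            t2 = (gx * xhat).sum(axis=(2, 3), keepdims=True) / m
            x._accumulate(inv * (gx - t1 - xhat * t2))

    return Tensor(out_data, parents=parents, backward=backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    if not _needs_grad(x):
        return Tensor(out_data)
    n, c, h, w = x.shape

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along axis 1 (channels for maps, features for vectors)."""
    out_data = np.concatenate([a.data, b.data], axis=1)
    if not _needs_grad(a, b):
        return Tensor(out_data)
    ca = a.shape[1]

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :ca])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, ca:])

    return Tensor(out_data, parents=(a, b), backward=backward)


def narrow_channels(x: Tensor, start: int, length: int) -> Tensor:
    """Slice [start, start+length) along axis 1."""
    out_data = x.data[:, start:start + length].copy()
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, start:start + length] = g
        x._accumulate(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine map on feature vectors: (N, F) @ (O, F).T + (O,)."""
    out_data = x.data @ weight.data.T + bias.data
    parents = (x, weight, bias)
    if not _needs_grad(*parents):
        return Tensor(out_data)

    def backward(g):
        if bias.requires_grad or bias._parents:
            bias._accumulate(g.sum(axis=0))
        if weight.requires_grad or weight._parents:
            weight._accumulate(g.T @ x.data)
        if x.requires_grad or x._parents:
            x._accumulate(g @ weight.data)

    return Tensor(out_data, parents=parents, backward=backward)


def batched_pointwise_conv(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1x1 convolution with per-sample kernels.

    x: (N, Ci, H, W); weight: (N, Co, Ci); bias: (N, Co).  Each sample n is
    convolved with its own generated kernel — the dynamic-head primitive.
    """
    n, ci, h, w = x.shape
    if weight.shape[0] != n or weight.shape[2] != ci:
        raise ValueError(f"batched_pointwise_conv: x has {ci} channels, "
                         f"weight shape {weight.shape}")
    out_data = np.einsum("noi,nihw->nohw", weight.data, x.data, optimize=True)
    out_data += bias.data[:, :, None, None]
    parents = (x, weight, bias)
    if not _needs_grad(*parents):
        return Tensor(out_data)

    def backward(g):
        if bias.requires_grad or bias._parents:
            bias._accumulate(g.sum(axis=(2, 3)))
        if weight.requires_grad or weight._parents:
            weight._accumulate(np.einsum("nohw,nihw->noi", g, x.data, optimize=True))
        if x.requires_grad or x._parents:
            x._accumulate(np.einsum("noi,nohw->nihw", weight.data, g, optimize=True))

    return Tensor(out_data, parents=parents, backward=backward)


def gather_channel(x: Tensor, indices) -> Tensor:
    """Select one channel per sample: (N, C, H, W), idx (N,) -> (N, 1, H, W).

    Used by the multi-head baseline to supervise only the annotated class's
    output channel; gradients flow back into the selected channel only.
    """
    idx = np.asarray(indices, dtype=np.intp)
    n = x.shape[0]
    if idx.shape != (n,):
        raise ValueError(f"gather_channel: need {n} indices, got {idx.shape}")
    out_data = x.data[np.arange(n), idx][:, None]
    if not _needs_grad(x):
        return Tensor(out_data)

    def backward(g):
        full = np.zeros_like(x.data)
        full[np.arange(n), idx] = g[:, 0]
        x._accumulate(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable.

    loss = mean( max(z,0) - z*t + log(1+exp(-|z|)) );  d/dz = (sigmoid(z)-t)/n
    """
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    if z.shape != t.shape:
        raise ValueError(f"bce_with_logits: shape mismatch {z.shape} vs {t.shape}")
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("bce_with_logits: non-finite logits")
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(per.mean(), dtype=z.dtype)
    if not _needs_grad(logits):
        return Tensor(out_data)

    def backward(g):
        logits._accumulate(g * (_logistic(z) - t) / z.size)

    return Tensor(out_data, parents=(logits,), backward=backward)


def soft_dice_loss(logits: Tensor, target: np.ndarray,
                   smooth: float = 1.0) -> Tensor:
    """Mean (over samples) soft-Dice loss 1 - (2 Σ p·t + s) / (Σ p + Σ t + s).

    `logits` has shape (N, ...); probabilities are the logistic of the
    logits; the sums run over all non-batch axes.
    """
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    if z.shape != t.shape:
        raise ValueError(f"soft_dice_loss: shape mismatch {z.shape} vs {t.shape}")
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("soft_dice_loss: non-finite logits")
    n = z.shape[0]
    zf = z.reshape(n, -1)
    tf = t.reshape(n, -1)
    p = _logistic(zf)
    inter = (p * tf).sum(axis=1)
    denom = p.sum(axis=1) + tf.sum(axis=1) + smooth
    dice = (2.0 * inter + smooth) / denom
    out_data = np.asarray((1.0 - dice).mean(), dtype=z.dtype)
    if not _needs_grad(logits):
        return Tensor(out_data)

    def backward(g):
        # d dice/dp = (2 t * denom - (2 inter + s)) / denom^2
        ddice_dp = (2.0 * tf * denom[:, None] - (2.0 * inter + smooth)[:, None]) \
            / (denom ** 2)[:, None]
        dloss_dp = -ddice_dp / n
        dz = dloss_dp * p * (1.0 - p)
        logits._accumulate(g * dz.reshape(z.shape))

    return Tensor(out_data, parents=(logits,), backward=backward)
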