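"""Minimal reverse-mode autodiff for 3D convolutional networks on numpy.

Implements exactly the operations the Dense-U-Net needs — 3D "same"
convolution, ReLU, 2x max-pooling, nearest-neighbour upsampling, channel
concatenation and a mean-squared-error head — each with a hand-written
backward pass, plus the Adam optimizer. Convolutions are evaluated as
im2col patch-matrix products so both passes run on BLAS; the gradient with
respect to the input reuses the same primitive with a spatially flipped,
channel-transposed kernel.

Tensors carry ``(C, D, H, W)`` float32 arrays. Gradient correctness is
established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv3d", "relu", "maxpool2", "upsample2", "concat", "mse", "backward", "Adam"]


class Tensor:
    """Node in the computation tape.

    ``grad_fn(grad_out)`` returns one gradient array per parent tensor.
    """

    __slots__ = ("data", "parents", "grad_fn", "grad")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        self.grad = None


def _conv_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """'Same'-padded correlation via one batched matmul + scatter-adds.

    All kernel offsets are evaluated in a single (k^3*C_out, C_in) @
    (C_in, Nvox) BLAS product on contiguous memory; each offset's slab is
    then added into a zero-padded output buffer at its shifted position.
    This avoids the strided im2col gather, which dominates run time for
    small channel counts.
    """
    c_out, c_in, k = w.shape[0], w.shape[1], w.shape[2]
    C, D, H, W = x.shape
    p = k // 2
    wmat = np.ascontiguousarray(w.transpose(2, 3, 4, 0, 1)).reshape(k**3 * c_out, c_in)
    y = (wmat @ x.reshape(c_in, -1)).reshape(k, k, k, c_out, D, H, W)
    buf = np.zeros((c_out, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
    for a in range(k):
        for bb in range(k):
            for cc in range(k):
                buf[:, 2 * p - a : 2 * p - a + D,
                    2 * p - bb : 2 * p - bb + H,
                    2 * p - cc : 2 * p - cc + W] += y[a, bb, cc]
    out = np.ascontiguousarray(buf[:, p : p + D, p : p + H, p : p + W])
    if b is not None:
        out += b[:, None, None, None]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 3D convolution: (C_in,D,H,W) x (C_out,C_in,k,k,k) -> (C_out,D,H,W)."""
    out = _conv_raw(x.data, w.data, b.data)
    k = w.data.shape[2]
    c_out = w.data.shape[0]

    def grad_fn(g):
        C, D, H, W = x.data.shape
        p = k // 2
        gflat = g.reshape(c_out, -1)
        db = gflat.sum(axis=1)
        # dW[o,c,offset] = sum_q x[c,q] * g[o, q - offset]; slide g (the
        # smaller tensor) over the contiguous input instead of vice versa
        xt = np.ascontiguousarray(x.data.reshape(C, -1).T)  # (Nvox, C)
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (p, p)))
        dw = np.empty_like(w.data)
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    sl = gp[:, 2 * p - a : 2 * p - a + D,
                            2 * p - bb : 2 * p - bb + H,
                            2 * p - cc : 2 * p - cc + W].reshape(c_out, -1)
                    dw[:, :, a, bb, cc] = sl @ xt
        # dx = correlation of g with the flipped, channel-transposed kernel
        w_t = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        dx = _conv_raw(g, w_t, None)
        return dx, dw, db

    return Tensor(out, (x, w, b), grad_fn)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def grad_fn(g):
        return (g * mask,)

    return Tensor(out, (x,), grad_fn)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; ties break to the first (lowest-index) maximum."""
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial sides, got {(D, H, W)}")
    win = (
        x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(C, D // 2, H // 2, W // 2, 8)
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        dx = (
            gwin.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W)
        )
        return (dx,)

    return Tensor(out, (x,), grad_fn)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along every spatial axis."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def grad_fn(g):
        C, D, H, W = x.data.shape
        dx = g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
        return (dx,)

    return Tensor(out, (x,), grad_fn)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis (dense-block wiring)."""
    out = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.data.shape[0] for t in tensors]

    def grad_fn(g):
        return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=0))

    return Tensor(out, tuple(tensors), grad_fn)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Per-voxel mean squared error against a constant target."""
    target = np.asarray(target, dtype=np.float32)
    diff = pred.data - target
    out = np.array(np.mean(diff.astype(np.float64) ** 2), dtype=np.float32)

    def grad_fn(g):
        return (g * 2.0 * diff / diff.size,)

    return Tensor(out, (pred,), grad_fn)


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep accumulating ``.grad`` on every tape node."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:  # iterative DFS; deep graphs overflow recursion limits
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node.grad_fn is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.grad_fn(node.grad)):
            g = g.astype(np.float32, copy=False)
            if parent.grad is None:
                parent.grad = g.copy()
            else:
                parent.grad += g


class Adam:
    """Adam with bias correction; first/second moments per parameter."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
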