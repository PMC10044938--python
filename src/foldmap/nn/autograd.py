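"""Compact reverse-mode autodiff on numpy arrays.

Implements exactly the operations the pairing-score network needs: stride-1
same-padding convolution, batch normalization, ReLU, 2x2 max-pool, 2x
nearest-neighbour upsampling, channel concatenation, elementwise add,
spatial transpose, zero-pad/crop, and a masked weighted binary
cross-entropy-with-logits loss.

Convolution is evaluated as a sum of kernel-offset shifts, each a single
BLAS matmul over flattened spatial positions. Compared with im2col this
keeps peak memory at O(C*H*W) instead of O(C*k^2*H*W), which matters for
long sequences (a 720 x 720 map with 146 input channels).

Tensors record their parents and a backward closure; ``backward()`` runs a
topological sweep. ``no_grad()`` disables graph building for inference.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # Free the graph eagerly: closures over cached arrays form reference
        # cycles that count-based GC reclaims too late for multi-step training
        # loops. Leaf tensors (parameters, inputs) keep their gradients.
        for t in topo:
            if t._backward is not None:
                t._backward = None
                t._parents = ()
                if t is not self:
                    t.grad = None

    def zero_grad(self) -> None:
        self.grad = None


def _make(data, parents, backward, requires=None) -> Tensor:
    req = any(p.requires_grad for p in parents) if requires is None else requires
    return Tensor(data, requires_grad=req, parents=parents, backward=backward)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise / structural ops

def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch: {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x.accumulate(g * mask)

    return _make(out_data, (x,), backward)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate (N, C, H, W) tensors along the channel axis."""
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.accumulate(g[:, lo:hi])

    return _make(out_data, tuple(tensors), backward)


def transpose_spatial(x: Tensor) -> Tensor:
    """Swap the two spatial axes of an (N, C, H, W) tensor."""
    out_data = np.ascontiguousarray(x.data.transpose(0, 1, 3, 2))

    def backward(g):
        x.accumulate(g.transpose(0, 1, 3, 2))

    return _make(out_data, (x,), backward)


def pad_spatial(x: Tensor, target_h: int, target_w: int) -> Tensor:
    """Zero-pad bottom/right to (target_h, target_w)."""
    n, c, h, w = x.shape
    if (h, w) == (target_h, target_w):
        return x
    out_data = np.zeros((n, c, target_h, target_w), dtype=np.float32)
    out_data[:, :, :h, :w] = x.data

    def backward(g):
        x.accumulate(g[:, :, :h, :w])

    return _make(out_data, (x,), backward)


def crop_spatial(x: Tensor, h: int, w: int) -> Tensor:
    n, c, H, W = x.shape
    if (H, W) == (h, w):
        return x
    out_data = np.ascontiguousarray(x.data[:, :, :h, :w])

    def backward(g):
        full = np.zeros((n, c, H, W), dtype=np.float32)
        full[:, :, :h, :w] = g
        x.accumulate(full)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 same-padding 2-D convolution.

    x: (N, C, H, W); w: (O, C, kh, kw) with odd kh, kw; b: (O,).
    Evaluated as one matmul per kernel offset on the zero-padded input.
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    ph, pw = kh // 2, kw // 2
    hp, wp = h + 2 * ph, wd + 2 * pw
    xp = np.zeros((n, c, hp, wp), dtype=np.float32)
    xp[:, :, ph : ph + h, pw : pw + wd] = x.data
    xp_flat = xp.reshape(n, c, hp * wp)
    out_data = np.empty((n, o, h, wd), dtype=np.float32)
    out_data[:] = b.data[None, :, None, None]
    if kh == kw == 1:
        out_data += np.matmul(w.data[:, :, 0, 0], x.data.reshape(n, c, h * wd)
                              ).reshape(n, o, h, wd)
    else:
        # one matmul per kernel tap on the padded grid, then shifted adds;
        # avoids materializing k^2 copies of the input
        tmp = np.empty((n, o, hp * wp), dtype=np.float32)
        for dy in range(kh):
            for dx in range(kw):
                np.matmul(w.data[:, :, dy, dx], xp_flat, out=tmp)
                out_data += tmp.reshape(n, o, hp, wp)[:, :, dy : dy + h,
                                                      dx : dx + wd]

    def backward(g):
        gf = g.reshape(n, o, h * wd)
        if b.requires_grad:
            b.accumulate(gf.sum(axis=(0, 2)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for dy in range(kh):
            for dx in range(kw):
                patch = xp[:, :, dy : dy + h, dx : dx + wd].reshape(n, c, h * wd)
                if dw is not None:
                    # (N, O, HW) @ (N, HW, C) -> sum over N -> (O, C)
                    dw[:, :, dy, dx] = np.matmul(
                        gf, patch.transpose(0, 2, 1)
                    ).sum(axis=0)
                if need_dx:
                    contrib = np.matmul(w.data[:, :, dy, dx].T, gf)
                    dxp[:, :, dy : dy + h, dx : dx + wd] += contrib.reshape(
                        n, c, h, wd
                    )
        if dw is not None:
            w.accumulate(dw)
        if need_dx:
            x.accumulate(dxp[:, :, ph : ph + h, pw : pw + wd])

    return _make(out_data, (x, w, b), backward)


# ---------------------------------------------------------------------------
# batch normalization

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    mask: Optional[np.ndarray] = None,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode statistics come from the batch (optionally restricted
    to ``mask``, a broadcastable 0/1 array excluding padded cells) and the
    running estimates are updated in place; in inference mode the running
    estimates are used.
    """
    if training:
        if mask is None:
            axes = (0, 2, 3)
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            count = x.data.size // x.data.shape[1]
        else:
            m = mask.astype(np.float32)
            count = float(m.sum() * (x.data.shape[0] if m.shape[0] == 1 else 1))
            msum = (x.data * m).sum(axis=(0, 2, 3))
            mean = msum / count
            var = ((x.data - mean[None, :, None, None]) ** 2 * m).sum(
                axis=(0, 2, 3)
            ) / count
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
        count = x.data.size // x.data.shape[1]

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    if mask is not None:
        out_data = out_data * mask

    def backward(g):
        if mask is not None:
            g = g * mask
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        scale = (gamma.data * inv_std)[None, :, None, None]
        if training:
            gm = g.mean(axis=(0, 2, 3)) if mask is None else (
                g.sum(axis=(0, 2, 3)) / count
            )
            gxm = (g * xhat).mean(axis=(0, 2, 3)) if mask is None else (
                (g * xhat).sum(axis=(0, 2, 3)) / count
            )
            dx = scale * (
                g - gm[None, :, None, None] - xhat * gxm[None, :, None, None]
            )
            if mask is not None:
                dx = dx * mask
        else:
            dx = scale * g
        x.accumulate(dx)

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resampling

def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = xr.max(axis=(3, 5))

    def backward(g):
        winners = xr == out_data[:, :, :, None, :, None]
        ties = winners.sum(axis=(3, 5), keepdims=True)
        dxr = winners * (g[:, :, :, None, :, None] / ties)
        x.accumulate(dxr.reshape(n, c, h, w))

    return _make(out_data, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    n, c, h, w = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x.accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# loss

def weighted_bce_with_logits(
    scores: Tensor,
    target: np.ndarray,
    valid_mask: np.ndarray,
    positive_weight: float = 1.0,
) -> Tensor:
    """Mean class-weighted binary cross-entropy over the valid cells.

    ``scores`` holds logits; ``target`` is 0/1; ``valid_mask`` selects the
    cells that participate (e.g. upper triangle at separation >= 4, inside
    the un-padded region). Positives are weighted by ``positive_weight``.
    """
    s = scores.data
    t = target.astype(np.float32)
    m = valid_mask.astype(np.float32)
    nvalid = float(m.sum())
    if nvalid == 0:
        raise ValueError("loss mask selects no cells")
    w = m * (1.0 + (positive_weight - 1.0) * t)
    # stable log-sigmoid: log(1+exp(-|s|)) + max(-s*sign, 0) forms
    log_sig = -np.logaddexp(0.0, -s)
    log_one_minus = -np.logaddexp(0.0, s)
    loss_cells = -(w * (t * log_sig + (1.0 - t) * log_one_minus))
    out_data = np.array(loss_cells.sum() / nvalid, dtype=np.float32)

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-s))
        scores.accumulate(g * w * (sig - t) / nvalid)

    return _make(out_data, (scores,), backward)
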