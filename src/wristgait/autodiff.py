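"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the sequence classifiers need:
dense algebra, gating nonlinearities, temporal convolution/pooling, and the
batched contractions used by multiplicative attention.  Gradients are
accumulated on a tape and released by :meth:`Tensor.backward`, which runs a
topological sort of the recorded graph.  The engine is dtype-agnostic:
float64 inputs give float64 gradients (used by the finite-difference checks),
training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node; ``grad`` defaults to ones."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deeper than Python's stack
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        a, b = self, _wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(a.data + b.data, parents=(a, b), backward=bw)

    def __mul__(self, other):
        a, b = self, _wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(a.data * b.data, parents=(a, b), backward=bw)

    def __sub__(self, other):
        return self + (_wrap(other) * -1.0)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other):
        a, b = self, _wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor(a.data @ b.data, parents=(a, b), backward=bw)

    __matmul__ = matmul


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def parameter(data):
    return Tensor(np.asarray(data), requires_grad=True)


# -- elementwise nonlinearities --------------------------------------------


def tanh(t):
    out = np.tanh(t.data)

    def bw(g):
        t._accum(g * (1.0 - out * out))

    return Tensor(out, parents=(t,), backward=bw)


def sigmoid(t):
    out = 1.0 / (1.0 + np.exp(-t.data))

    def bw(g):
        t._accum(g * out * (1.0 - out))

    return Tensor(out, parents=(t,), backward=bw)


def relu(t):
    mask = t.data > 0

    def bw(g):
        t._accum(g * mask)

    return Tensor(t.data * mask, parents=(t,), backward=bw)


def dropout(t, rate, rng, training):
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return t
    keep = (rng.random(t.data.shape) >= rate).astype(t.data.dtype)
    scale = 1.0 / (1.0 - rate)

    def bw(g):
        t._accum(g * keep * scale)

    return Tensor(t.data * keep * scale, parents=(t,), backward=bw)


# -- shape surgery ----------------------------------------------------------


def concat_cols(a, b):
    """Concatenate two (B, n) tensors along the feature axis."""
    na = a.data.shape[1]

    def bw(g):
        if a.requires_grad:
            a._accum(g[:, :na])
        if b.requires_grad:
            b._accum(g[:, na:])

    return Tensor(
        np.concatenate([a.data, b.data], axis=1), parents=(a, b), backward=bw
    )


def slice_cols(t, start, stop):
    def bw(g):
        full = np.zeros_like(t.data)
        full[:, start:stop] = g
        t._accum(full)

    return Tensor(t.data[:, start:stop], parents=(t,), backward=bw)


def stack_time(tensors):
    """Stack T tensors of shape (B, h) into (B, T, h)."""
    ts = list(tensors)

    def bw(g):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(g[:, i, :])

    return Tensor(
        np.stack([t.data for t in ts], axis=1), parents=tuple(ts), backward=bw
    )


# -- attention contractions -------------------------------------------------


def bdot(u, s):
    """out[b, t] = sum_h u[b, h] * s[b, t, h]  (scores of query vs states)."""

    def bw(g):
        if u.requires_grad:
            u._accum(np.einsum("bt,bth->bh", g, s.data))
        if s.requires_grad:
            s._accum(np.einsum("bt,bh->bth", g, u.data))

    return Tensor(
        np.einsum("bh,bth->bt", u.data, s.data), parents=(u, s), backward=bw
    )


def wsum(w, s):
    """out[b, h] = sum_t w[b, t] * s[b, t, h]  (attention-weighted context)."""

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bh,bth->bt", g, s.data))
        if s.requires_grad:
            s._accum(np.einsum("bt,bh->bth", w.data, g))

    return Tensor(
        np.einsum("bt,bth->bh", w.data, s.data), parents=(w, s), backward=bw
    )


def slice_time(t, idx):
    """Pick time step ``idx`` from a (B, T, h) tensor -> (B, h)."""

    def bw(g):
        full = np.zeros_like(t.data)
        full[:, idx, :] = g
        t._accum(full)

    return Tensor(t.data[:, idx, :], parents=(t,), backward=bw)


def softmax_rows(t):
    """Row-wise softmax over the last axis of a (B, T) tensor."""
    z = t.data - t.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=-1, keepdims=True)
        t._accum(out * (g - dot))

    return Tensor(out, parents=(t,), backward=bw)


def softmax_cross_entropy(logits, onehot):
    """Mean categorical cross-entropy, fused with softmax for stability.

    Returns ``(loss, probs)`` where ``loss`` is a 0-d Tensor and ``probs``
    the softmax probabilities as a plain ndarray.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    m = logits.data.shape[0]
    clipped = np.clip(probs, 1e-12, 1.0)
    loss_val = -(onehot * np.log(clipped)).sum() / m

    def bw(g):
        logits._accum(g * (probs - onehot) / m)

    return Tensor(loss_val, parents=(logits,), backward=bw), probs


# -- temporal convolution / pooling ----------------------------------------


def conv1d_same(x, w, b, kernel_size):
    """Same-padded stride-1 temporal convolution.

    x: (B, T, Cin); w: (kernel_size * Cin, Cout); b: (Cout,).
    """
    B, T, Cin = x.data.shape
    k = kernel_size
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, k - 1 - pad), (0, 0)))
    # cols[b, t, j, c] = xp[b, t + j, c]
    cols = np.stack([xp[:, j : j + T, :] for j in range(k)], axis=2)
    flat = cols.reshape(B * T, k * Cin)
    out = (flat @ w.data + b.data).reshape(B, T, -1)

    def bw(g):
        gf = g.reshape(B * T, -1)
        if w.requires_grad:
            w._accum(flat.T @ gf)
        if b.requires_grad:
            b._accum(gf.sum(axis=0))
        if x.requires_grad:
            gcols = (gf @ w.data.T).reshape(B, T, k, Cin)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j : j + T, :] += gcols[:, :, j, :]
            x._accum(gxp[:, pad : pad + T, :])

    return Tensor(out, parents=(x, w, b), backward=bw)


def maxpool1d(x, width=2):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""
    B, T, C = x.data.shape
    To = T // width
    trimmed = x.data[:, : To * width, :].reshape(B, To, width, C)
    arg = trimmed.argmax(axis=2)
    out = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def bw(g):
        gx = np.zeros((B, To, width, C), dtype=g.dtype)
        np.put_along_axis(gx, arg[:, :, None, :], g[:, :, None, :], axis=2)
        full = np.zeros_like(x.data)
        full[:, : To * width, :] = gx.reshape(B, To * width, C)
        x._accum(full)

    return Tensor(out, parents=(x,), backward=bw)


def mean_over_time(x):
    """Global average pooling: (B, T, C) -> (B, C)."""
    T = x.data.shape[1]

    def bw(g):
        x._accum(np.broadcast_to(g[:, None, :] / T, x.data.shape).copy())

    return Tensor(x.data.mean(axis=1), parents=(x,), backward=bw)
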