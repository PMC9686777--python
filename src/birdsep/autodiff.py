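"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is infrastructure, not science: it provides exactly the operations the
separation network needs (batched matmul, 1-D convolution and its transpose,
softmax, elementwise arithmetic, reductions and shape ops) with hand-written
backward rules, plus an Adam optimizer.  Gradients are accumulated by a
topological-order sweep over the recorded computation graph.

All operations follow the dtype of their inputs, so the same graph runs in
float32 for training speed and float64 when tests need tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] += pg
                    else:
                        grads[id(p)] = pg
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _t(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_t(other, self.data.dtype))

    def __rsub__(self, other):
        return _t(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _t(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _t(other, self.data.dtype)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _t(other, self.data.dtype) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(
            out_data, (a,), lambda g: (g * out_data * (1 - out_data),)
        )

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * 0.5 / out_data,))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._make(out, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            out = np.zeros_like(a.data)
            out[idx] = g
            return (out,)

        return Tensor._make(a.data[idx], (a,), bw)

    def pad1d(self, before: int, after: int):
        """Zero-pad the last axis."""
        a = self
        width = [(0, 0)] * (a.data.ndim - 1) + [(before, after)]
        T = a.data.shape[-1]

        def bw(g):
            sl = (slice(None),) * (a.data.ndim - 1) + (slice(before, before + T),)
            return (g[sl],)

        return Tensor._make(np.pad(a.data, width), (a,), bw)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other):
        other = _t(other)
        a, b = self, other

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._make(y, (a,), bw)

    # -- convolutions ------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1):
        """Cross-correlation along the last axis.

        self: (B, Cin, T); weight: (Cout, Cin, k); output (B, Cout, L) with
        L = (T - k)//stride + 1.
        """
        a, w = self, weight
        B, Cin, T = a.data.shape
        Cout, Cin_w, k = w.data.shape
        if Cin != Cin_w:
            raise ValueError(f"conv1d channel mismatch: input {Cin}, weight {Cin_w}")
        if T < k:
            raise ValueError(f"conv1d input length {T} shorter than kernel {k}")
        L = (T - k) // stride + 1
        x = np.ascontiguousarray(a.data)
        st = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, (B, Cin, k, L), (st[0], st[1], st[2], st[2] * stride)
        ).reshape(B, Cin * k, L)
        out = w.data.reshape(Cout, Cin * k) @ cols
        if bias is not None:
            out = out + bias.data[:, None]

        def bw(g):
            gw = (g @ cols.transpose(0, 2, 1)).sum(axis=0).reshape(Cout, Cin, k)
            dcols = (w.data.reshape(Cout, Cin * k).T @ g).reshape(B, Cin, k, L)
            gx = np.zeros_like(x)
            for j in range(k):
                gx[:, :, j : j + stride * L : stride] += dcols[:, :, j, :]
            gb = None if bias is None else g.sum(axis=(0, 2))
            return (gx, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out, parents, bw)

    def dwconv1d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1):
        """Depthwise cross-correlation: one k-tap filter per channel.

        self: (B, C, T); weight: (C, k); output (B, C, L).
        """
        a, w = self, weight
        B, C, T = a.data.shape
        C_w, k = w.data.shape
        if C != C_w:
            raise ValueError(f"dwconv1d channel mismatch: input {C}, weight {C_w}")
        if T < k:
            raise ValueError(f"dwconv1d input length {T} shorter than kernel {k}")
        L = (T - k) // stride + 1
        x = np.ascontiguousarray(a.data)
        st = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, (B, C, k, L), (st[0], st[1], st[2], st[2] * stride)
        )
        out = np.einsum("bckl,ck->bcl", cols, w.data)
        if bias is not None:
            out = out + bias.data[:, None]

        def bw(g):
            gw = np.einsum("bckl,bcl->ck", cols, g)
            gx = np.zeros_like(x)
            for j in range(k):
                gx[:, :, j : j + stride * L : stride] += g * w.data[:, j][:, None]
            gb = None if bias is None else g.sum(axis=(0, 2))
            return (gx, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out, parents, bw)

    def dwconv_transpose1d(
        self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1
    ):
        """Depthwise transposed convolution.

        self: (B, C, L); weight: (C, k); output (B, C, (L-1)*stride + k).
        """
        a, w = self, weight
        B, C, L = a.data.shape
        C_w, k = w.data.shape
        if C != C_w:
            raise ValueError(
                f"dwconv_transpose1d channel mismatch: input {C}, weight {C_w}"
            )
        T = (L - 1) * stride + k
        out = np.zeros((B, C, T), dtype=a.data.dtype)
        for j in range(k):
            out[:, :, j : j + stride * L : stride] += a.data * w.data[:, j][:, None]
        if bias is not None:
            out = out + bias.data[:, None]

        def bw(g):
            g = np.ascontiguousarray(g)
            st = g.strides
            gcols = np.lib.stride_tricks.as_strided(
                g, (B, C, k, L), (st[0], st[1], st[2], st[2] * stride)
            )
            gx = np.einsum("bckl,ck->bcl", gcols, w.data)
            gw = np.einsum("bckl,bcl->ck", gcols, a.data)
            gb = None if bias is None else g.sum(axis=(0, 2))
            return (gx, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out, parents, bw)

    def conv_transpose1d(
        self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1
    ):
        """Transposed convolution (gradient of conv1d w.r.t. its input).

        self: (B, Cin, L); weight: (Cin, Cout, k); output (B, Cout, T) with
        T = (L - 1)*stride + k.
        """
        a, w = self, weight
        B, Cin, L = a.data.shape
        Cin_w, Cout, k = w.data.shape
        if Cin != Cin_w:
            raise ValueError(
                f"conv_transpose1d channel mismatch: input {Cin}, weight {Cin_w}"
            )
        T = (L - 1) * stride + k
        t = (w.data.reshape(Cin, Cout * k).T @ a.data).reshape(B, Cout, k, L)
        out = np.zeros((B, Cout, T), dtype=t.dtype)
        for j in range(k):
            out[:, :, j : j + stride * L : stride] += t[:, :, j, :]
        if bias is not None:
            out = out + bias.data[:, None]

        def bw(g):
            g = np.ascontiguousarray(g)
            st = g.strides
            gcols = np.lib.stride_tricks.as_strided(
                g, (B, Cout, k, L), (st[0], st[1], st[2], st[2] * stride)
            ).reshape(B, Cout * k, L)
            gx = w.data.reshape(Cin, Cout * k) @ gcols
            gw = (gcols @ a.data.transpose(0, 2, 1)).sum(axis=0)
            gw = gw.reshape(Cout, k, Cin).transpose(2, 0, 1)
            gb = None if bias is None else g.sum(axis=(0, 2))
            return (gx, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out, parents, bw)


def _t(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.ndim == 0 and dtype is not None:
        arr = arr.astype(dtype)
    return Tensor(arr)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Adam:
    """Adam with the conventional defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - (
                self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            ).astype(p.data.dtype)
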