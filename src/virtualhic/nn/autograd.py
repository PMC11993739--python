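"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This backs the CNN-Transformer contact predictor and the tile denoiser.
Tensors wrap ndarrays and record a backward closure; ``Tensor.backward()``
topologically sorts the tape and accumulates gradients. Broadcasting is
supported by summing gradients back to the operand shape. Convolutions are
implemented as short explicit loops over the (small) kernel extent so each
step is a large BLAS contraction.

Performance note: backward closures pass ``own=True`` to ``_accum`` when
the gradient array is freshly allocated and unaliased, letting the engine
store it without a defensive copy; views and pass-through gradients are
copied on first accumulation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "conv1d", "conv2d", "no_grad"]


class _NoGrad:
    enabled = False

    def __enter__(self):
        self.prev = _NoGrad.enabled
        _NoGrad.enabled = True

    def __exit__(self, *exc):
        _NoGrad.enabled = self.prev


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]):
    """Sum ``grad`` down to ``shape``; returns (array, freshly_allocated)."""
    if grad.shape == shape:
        return grad, False
    extra = grad.ndim - len(shape)
    fresh = False
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
        fresh = True
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
        fresh = True
    return grad.reshape(shape), fresh


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(x)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers to our __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and not _NoGrad.enabled
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad.enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    # python scalars take a fast path that preserves float32 operands
    # (numpy weak-scalar promotion) and skips the constant's tape node
    def __add__(self, other):
        if isinstance(other, (int, float)):
            c = float(other)

            def backward(g):
                self._accum(g)

            return Tensor._make(self.data + c, (self,), backward)
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(*_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(*_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g, own=True)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-float(other))
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + float(other)
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = float(other)

            def backward(g):
                self._accum(g * c, own=True)

            return Tensor._make(self.data * c, (self,), backward)
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(*_own_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(*_own_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / float(other))
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(*_own_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    *_own_unbroadcast(-g * self.data / other.data**2,
                                      other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            c = float(other)

            def backward(g):
                self._accum(-g * c / self.data**2, own=True)

            return Tensor._make(c / self.data, (self,), backward)
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1), own=True)

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(*_own_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(*_own_unbroadcast(gb, other.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other),
                            backward)

    # -- elementwise functions ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g / (2 * out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1 - out_data**2), own=True)

        return Tensor._make(out_data, (self,), backward)

    def erf(self):
        def backward(g):
            self._accum(g * float(2 / np.sqrt(np.pi)) * np.exp(-self.data**2),
                        own=True)

        return Tensor._make(_erf(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1 - out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Gaussian-error-linear unit (tanh approximation,
        0.5·x·(1+tanh(√(2/π)·(x+0.044715·x³))) — the fast variant used by
        most transformer implementations)."""
        x = self.data
        c = float(np.sqrt(2 / np.pi))
        u = c * (x + 0.044715 * x**3)
        t = np.tanh(u)
        out_data = 0.5 * x * (1 + t)

        def backward(g):
            du = c * (1 + 3 * 0.044715 * x**2)
            d = 0.5 * (1 + t) + 0.5 * x * (1 - t**2) * du
            self._accum(g * d, own=True)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask, own=True)

        return Tensor._make(self.data * mask, (self,), backward)

    def clip(self, lo: float, hi: float):
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * inside, own=True)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy(), own=True)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy(), own=True)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))  # view: engine copies on first use

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.ascontiguousarray(np.swapaxes(g, a, b)), own=True)

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def transpose(self, axes):
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accum(np.ascontiguousarray(np.transpose(g, inv)), own=True)

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full, own=True)

        return Tensor._make(self.data[idx], (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot), own=True)

        return Tensor._make(out_data, (self,), backward)

    # -- engine ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _own_unbroadcast(fresh: np.ndarray, shape):
    arr, _ = _unbroadcast(fresh, shape)
    return arr, True  # input array is freshly allocated either way


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])  # view: copied on first accumulation

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K); output (B, C_out, L).
    """
    B, C_in, L = x.shape
    C_out, C_in2, K = w.shape
    if C_in != C_in2:
        raise ValueError(f"channel mismatch {C_in} vs {C_in2}")
    pad_l = (K - 1) // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_l, pad_r)))
    out_data = np.zeros((B, C_out, L),
                        dtype=np.promote_types(x.data.dtype, w.data.dtype))
    for k in range(K):
        out_data += np.einsum(
            "bcl,oc->bol", xp[:, :, k : k + L], w.data[:, :, k], optimize=True
        )
    if b is not None:
        out_data += b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + L] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True
                )
            x._accum(np.ascontiguousarray(gxp[:, :, pad_l : pad_l + L]),
                     own=True)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for k in range(K):
                gw[:, :, k] = np.einsum(
                    "bol,bcl->oc", g, xp[:, :, k : k + L], optimize=True
                )
            w._accum(gw, own=True)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)), own=True)

    return Tensor._make(out_data, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 2-D convolution. ``x``: (B, C_in, H, W); ``w``:
    (C_out, C_in, KH, KW)."""
    B, C_in, H, W = x.shape
    C_out, C_in2, KH, KW = w.shape
    if C_in != C_in2:
        raise ValueError("channel mismatch")
    ph, pw = (KH - 1) // 2, (KW - 1) // 2
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (ph, KH - 1 - ph), (pw, KW - 1 - pw))
    )
    out_data = np.zeros((B, C_out, H, W),
                        dtype=np.promote_types(x.data.dtype, w.data.dtype))
    for i in range(KH):
        for j in range(KW):
            out_data += np.einsum(
                "bchw,oc->bohw",
                xp[:, :, i : i + H, j : j + W],
                w.data[:, :, i, j],
                optimize=True,
            )
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    gxp[:, :, i : i + H, j : j + W] += np.einsum(
                        "bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accum(
                np.ascontiguousarray(gxp[:, :, ph : ph + H, pw : pw + W]),
                own=True,
            )
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(KH):
                for j in range(KW):
                    gw[:, :, i, j] = np.einsum(
                        "bohw,bchw->oc",
                        g,
                        xp[:, :, i : i + H, j : j + W],
                        optimize=True,
                    )
            w._accum(gw, own=True)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)), own=True)

    return Tensor._make(out_data, parents, backward)
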