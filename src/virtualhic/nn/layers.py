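"""Neural-network layers and the Adam optimizer on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, conv2d

__all__ = [
    "Module", "Linear", "Conv1d", "Conv2d", "BatchNorm", "LayerNorm",
    "MaxPool1d", "GELU", "Sequential", "SelfAttention",
    "TransformerEncoderLayer", "Adam", "sinusoidal_positions",
]


class Module:
    """Minimal container: tracks parameters through attributes and lists."""

    training = True

    def parameters(self) -> list[Tensor]:
        out, seen = [], set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return out

    def modules(self) -> list["Module"]:
        out = [self]

        def visit(obj):
            if isinstance(obj, Module):
                out.append(obj)
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        for v in vars(self).values():
            visit(v)
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=p.data.dtype).copy()

    def astype(self, dtype) -> "Module":
        """Cast parameters and batchnorm running statistics in place."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = m.running_mean.astype(dtype)
                m.running_var = m.running_var.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _he(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            lead = x.shape[:-1]
            flat = x.reshape(-1, x.shape[-1])
            return (flat @ self.w + self.b).reshape(*lead, self.w.shape[1])
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        self.w = _he(rng, (c_out, c_in, kernel), c_in * kernel)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        self.w = _he(rng, (c_out, c_in, kernel, kernel), c_in * kernel**2)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1).

    Works for (B, C, L) and (B, C, H, W); keeps running statistics for
    deterministic evaluation.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MaxPool1d(Module):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        if self.factor == 1:
            return x
        B, C, L = x.shape
        f = self.factor
        if L % f:
            raise ValueError(f"length {L} not divisible by pool factor {f}")
        return x.reshape(B, C, L // f, f).max_last()


def _max_last(self: Tensor) -> Tensor:
    """Max over the trailing axis (used by pooling)."""
    idx = self.data.argmax(axis=-1)
    out_data = np.take_along_axis(self.data, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        full = np.zeros_like(self.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        self._accum(full)

    return Tensor._make(out_data, (self,), backward)


Tensor.max_last = _max_last  # type: ignore[attr-defined]


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class SelfAttention(Module):
    """Multi-head scaled-dot-product self-attention over (B, L, D)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        h = self.heads
        dh = D // h

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block: LN→attention→residual, LN→MLP→residual."""

    def __init__(self, dim: int, heads: int, ff_dim: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).gelu())


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data * (1.0 - self.lr * self.weight_decay)
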