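"""Neural-network building blocks and the Adam optimizer.

Layers follow the usual conventions: batch-first tensors, Glorot-uniform
weight init drawn from an explicit ``numpy.random.Generator`` so that a
single seed pins every parameter.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, cat

__all__ = [
    "Module", "Linear", "Conv1d", "LayerNorm", "Dropout", "GRU", "Adam",
    "sinusoidal_positions",
]


class Module:
    """Base class: parameter discovery + train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, (list, tuple)):
                params.extend(p for p in v if isinstance(p, Parameter))
            elif isinstance(v, dict):
                params.extend(p for p in v.values() if isinstance(p, Parameter))
        for child in self._children():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children():
            c.eval()
        return self

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.copy()


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, d_out, d_in).T)  # stored (d_in, d_out)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    """Same-padded 1-D convolution over (B, C, L) tensors; odd kernel only."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {kernel}")
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(c_out, c_in, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask randomness comes from
    the generator handed in at construction so runs stay reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class _GRULayer(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_hidden = d_hidden
        self.w_ih = Parameter(_glorot(rng, 3 * d_hidden, d_in).T)
        self.w_hh = Parameter(_glorot(rng, 3 * d_hidden, d_hidden).T)
        self.b_ih = Parameter(np.zeros(3 * d_hidden))
        self.b_hh = Parameter(np.zeros(3 * d_hidden))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d_in) -> outputs (B, T, d_hidden)."""
        b, t, _ = x.shape
        h = Tensor(np.zeros((b, self.d_hidden)))
        d = self.d_hidden
        outs = []
        for step in range(t):
            xt = x[:, step, :]
            gi = xt @ self.w_ih + self.b_ih
            gh = h @ self.w_hh + self.b_hh
            r = (gi[:, :d] + gh[:, :d]).sigmoid()
            z = (gi[:, d:2 * d] + gh[:, d:2 * d]).sigmoid()
            n = (gi[:, 2 * d:] + r * gh[:, 2 * d:]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h.reshape(b, 1, d))
        return cat(outs, axis=1)


class GRU(Module):
    """Stacked unidirectional GRU, batch-first."""

    def __init__(self, d_in: int, d_hidden: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        if n_layers < 1:
            raise ValueError("GRU needs at least one layer")
        self.layers = [
            _GRULayer(d_in if i == 0 else d_hidden, d_hidden, rng)
            for i in range(n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def final_state(self, x: Tensor) -> Tensor:
        """Last time-step output of the top layer: (B, d_hidden)."""
        return self(x)[:, -1, :]


def sinusoidal_positions(n_tokens: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional encoding table, shape (n_tokens, d_model)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
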