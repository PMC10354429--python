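"""Neural building blocks on top of :mod:`evmp.nn.autograd`.

Contains exactly the pieces the promoter-strength encoders need: dense
layers, a single-layer LSTM, layer normalisation, multi-head self-attention
blocks, and Adam with decoupled weight decay.  Parameter initialisation is
driven by an explicit numpy Generator so models are reproducible per seed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autograd import Tensor, concat, stack, unbind


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(value, requires_grad=True)


class Module:
    """Parameter container with recursive discovery (torch-like minimal)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.value = np.asarray(a, dtype=float).copy()


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for item in value:
            out.extend(_collect(item))
        return out
    return []


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Module):
    """Single-layer LSTM over inputs of shape (batch, time, features).

    ``__call__`` returns the stacked hidden states ``(batch, time, hidden)``;
    the final time step is the usual sequence embedding.  The whole unrolled
    cell is a single fused autodiff node: the forward pass caches gate
    activations and the backward pass is classic vectorised
    backpropagation-through-time, which keeps training fast without a
    per-step op graph.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        # gate order: input, forget, cell candidate, output
        self.w = Parameter(_glorot(rng, input_size + hidden_size,
                                   4 * hidden_size))
        bias = np.zeros(4 * hidden_size)
        bias[hidden_size:2 * hidden_size] = 1.0  # forget-gate bias
        self.bias = Parameter(bias)

    def __call__(self, x: Tensor) -> Tensor:
        xv = x.value
        batch, time, _ = xv.shape
        H = self.hidden_size
        I = self.input_size
        W, b = self.w.value, self.bias.value
        h = np.zeros((batch, H))
        c = np.zeros((batch, H))
        hs = np.empty((batch, time, H))
        cache = []  # per step: (z, i, f, g, o, c_prev, c)
        for t in range(time):
            z = np.concatenate([xv[:, t, :], h], axis=1)
            gates = z @ W + b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            hs[:, t, :] = h
            cache.append((z, i, f, g, o, c_prev, c))

        out = Tensor(hs, _parents=(x, self.w, self.bias))

        def backward(grad: np.ndarray) -> None:
            dW = np.zeros_like(W)
            db = np.zeros_like(b)
            dx = np.zeros_like(xv)
            dh_next = np.zeros((batch, H))
            dc_next = np.zeros((batch, H))
            for t in range(time - 1, -1, -1):
                z, i, f, g, o, c_prev, c_t = cache[t]
                tc = np.tanh(c_t)
                dh = grad[:, t, :] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1 - tc ** 2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz_gates = np.concatenate([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ], axis=1)
                dW += z.T @ dz_gates
                db += dz_gates.sum(axis=0)
                dzh = dz_gates @ W.T
                dx[:, t, :] = dzh[:, :I]
                dh_next = dzh[:, I:]
                dc_next = dc * f
            self.w._accumulate(dW)
            self.bias._accumulate(db)
            if x.requires_grad or x._parents:
                x._accumulate(dx)

        out._backward = backward
        return out


class SelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        batch, time, d_model = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(batch, time, self.n_heads,
                             self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.d_head ** -0.5)
        attn = scores.softmax(axis=-1)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, time, d_model)
        return self.out(mixed)


class TransformerLayer(Module):
    """Pre-norm transformer encoder block (attention + position-wise FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.attn = SelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


class Adam:
    """Adam with decoupled L2 weight decay (the Eq.-style lambda‖w‖² term)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for idx, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g * g
            m_hat = self.m[idx] / (1 - self.b1 ** self.t)
            v_hat = self.v[idx] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps)
                + 2.0 * self.weight_decay * p.value
            )
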