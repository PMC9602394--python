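"""Neural-network building blocks on top of :mod:`nestner.autograd`.

Contains the layers the dual-stream recognizer is assembled from: embedding
tables, linear maps, a one-hidden-layer perceptron, an LSTM run over padded
batches, a bidirectional wrapper, multi-head scaled dot-product
self-attention, inverted dropout and the Adam optimizer.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, concat, stack

__all__ = [
    "Module",
    "Embedding",
    "Linear",
    "MLP",
    "LSTM",
    "BiLSTM",
    "MultiHeadSelfAttention",
    "Dropout",
    "Adam",
    "reverse_padded",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in seen:
                    seen.add(id(value))
                    yield value
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        yield p
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                yield p
                    elif isinstance(item, Tensor) and item.requires_grad:
                        if id(item) not in seen:
                            seen.add(id(item))
                            yield item

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError(f"state mismatch: {len(params)} parameters, {len(arrays)} arrays")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Embedding(Module):
    """Trainable lookup table; rows indexed by integer ids."""

    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        self.weight = Tensor(rng.uniform(-scale, scale, size=(n_symbols, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(ids, dtype=np.int64))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """One hidden tanh layer followed by a linear map."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


def reverse_padded(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Reverse each row of a padded (B, T, D) tensor within its true length.

    Padding positions stay where they are, so a left-aligned padded batch
    stays left-aligned after reversal.
    """
    B, T = x.shape[0], x.shape[1]
    t = np.arange(T)[None, :]
    lens = np.asarray(lengths)[:, None]
    idx = np.where(t < lens, lens - 1 - t, t)
    return x.take_along_time(idx)


class LSTM(Module):
    """Unidirectional LSTM over a padded batch (B, T, D) with per-row lengths.

    Gates follow the standard formulation: input, forget and output gates are
    logistic functions of ``W·[h_{t-1}; x_t] + b``; the candidate state uses
    tanh; the cell update is ``c_t = f_t ⊙ c_{t-1} + i_t ⊙ u_t`` and the
    output ``h_t = o_t ⊙ tanh(c_t)``.  Separate weight matrices per gate.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        d_cat = d_in + d_hidden
        self.W_i = Tensor(_glorot(rng, d_cat, d_hidden), requires_grad=True)
        self.W_f = Tensor(_glorot(rng, d_cat, d_hidden), requires_grad=True)
        self.W_u = Tensor(_glorot(rng, d_cat, d_hidden), requires_grad=True)
        self.W_o = Tensor(_glorot(rng, d_cat, d_hidden), requires_grad=True)
        self.b_i = Tensor(np.zeros(d_hidden), requires_grad=True)
        # forget bias 1.0: standard remedy against early vanishing memory
        self.b_f = Tensor(np.ones(d_hidden), requires_grad=True)
        self.b_u = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.b_o = Tensor(np.zeros(d_hidden), requires_grad=True)

    def step(self, x_t: Tensor, h_prev: Tensor, c_prev: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([h_prev, x_t], axis=1)
        i = (z @ self.W_i + self.b_i).sigmoid()
        f = (z @ self.W_f + self.b_f).sigmoid()
        u = (z @ self.W_u + self.b_u).tanh()
        o = (z @ self.W_o + self.b_o).sigmoid()
        c = f * c_prev + i * u
        h = o * c.tanh()
        return h, c

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        if lengths is None:
            lengths = np.full(B, T, dtype=np.int64)
        lengths = np.asarray(lengths)
        H = self.d_hidden
        # one fused gate matmul per step instead of four
        W = concat([self.W_i, self.W_f, self.W_u, self.W_o], axis=1)
        b = concat([self.b_i, self.b_f, self.b_u, self.b_o], axis=0)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        for t in range(T):
            active = t < lengths
            if not active.any():
                outs.append(h)
                continue
            z = concat([h, x[:, t, :]], axis=1)
            g = z @ W + b
            i = g[:, :H].sigmoid()
            f = g[:, H:2 * H].sigmoid()
            u = g[:, 2 * H:3 * H].tanh()
            o = g[:, 3 * H:].sigmoid()
            c_new = f * c + i * u
            h_new = o * c_new.tanh()
            if active.all():
                h, c = h_new, c_new
            else:  # carry state through padded rows
                m = Tensor(active.astype(np.float64)[:, None])
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
            outs.append(h)
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Forward and backward LSTM passes concatenated per position."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        if lengths is None:
            lengths = np.full(x.shape[0], x.shape[1], dtype=np.int64)
        h_f = self.fwd(x, lengths)
        h_b = reverse_padded(self.bwd(reverse_padded(x, lengths), lengths), lengths)
        return concat([h_f, h_b], axis=2)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``h`` heads.

    ``Attention(Q, K, V) = softmax(QKᵀ/√d_k) V`` per head; head outputs are
    concatenated and linearly projected.  Padded key positions receive a
    large negative logit so their attention weight is numerically zero.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"model dim {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.W_q = Linear(d_model, d_model, rng, bias=False)
        self.W_k = Linear(d_model, d_model, rng, bias=False)
        self.W_v = Linear(d_model, d_model, rng, bias=False)
        self.W_o = Linear(d_model, d_model, rng, bias=False)

    def _split_heads(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        q = self._split_heads(self.W_q(x))
        k = self._split_heads(self.W_k(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) / math.sqrt(self.d_k)
        if mask is not None:
            bias = np.where(np.asarray(mask, dtype=bool), 0.0, -1e9)[:, None, None, :]
            scores = scores + Tensor(bias)
        return scores.softmax(axis=-1)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape
        weights = self.attention_weights(x, mask)
        v = self._split_heads(self.W_v(x))
        heads = (weights @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.W_o(heads)


class Dropout(Module):
    """Inverted dropout; identity when ``training`` is False or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Adam:
    """Adam optimizer with optional global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
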