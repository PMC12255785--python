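"""Neural building blocks for the distribution forecaster.

Implements the pieces of a standard encoder–decoder attention network
(multi-head attention, position-wise feed-forward blocks, layer
normalisation, sinusoidal positional encoding) plus an RMSProp optimiser,
all on the reverse-mode autodiff engine in :mod:`betadrift._autodiff`.

Weight initialisation, dropout masks and everything else stochastic draw
from a single ``numpy.random.Generator``, so a model built twice from the
same seed is bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "EncoderLayer",
    "DecoderLayer",
    "EncoderDecoder",
    "sinusoidal_positional_encoding",
    "RMSProp",
]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.linear(self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = centered.pow(2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gain + self.shift


class Dropout:
    """Inverted dropout; masks are drawn from the shared generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * mask


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(
                f"n_heads={n_heads} must divide d_model={d_model}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        b, tq, d_model = query.shape
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        context = (attn @ v).swapaxes(1, 2).reshape(b, tq, d_model)
        return self.wo(context)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(Module):
    def __init__(self, d_model, n_heads, d_ff, dropout, rng):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x, x), training))
        x = self.norm2(x + self.drop(self.ff(x), training))
        return x


class DecoderLayer(Module):
    def __init__(self, d_model, n_heads, d_ff, dropout, rng):
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, memory: Tensor, training: bool) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x, x), training))
        x = self.norm2(x + self.drop(self.cross_attn(x, memory, memory), training))
        x = self.norm3(x + self.drop(self.ff(x), training))
        return x


def sinusoidal_positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine position table, shape ``(max_len, d_model)``."""
    position = np.arange(max_len)[:, None]
    div = np.exp(np.arange(0, d_model, 2) * (-math.log(10000.0) / d_model))
    table = np.zeros((max_len, d_model))
    table[:, 0::2] = np.sin(position * div)
    table[:, 1::2] = np.cos(position * div[: table[:, 1::2].shape[1]])
    return table


class EncoderDecoder(Module):
    """Encoder–decoder attention stack run non-autoregressively.

    The same (position-encoded) sequence is fed as both source and target,
    no causal mask is applied, and the decoder's representation of the last
    position summarises the sequence.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 n_encoder_layers: int, n_decoder_layers: int,
                 dropout: float, rng: np.random.Generator,
                 max_len: int = 64):
        self.encoder_layers = [
            EncoderLayer(d_model, n_heads, d_ff, dropout, rng)
            for _ in range(n_encoder_layers)
        ]
        self.decoder_layers = [
            DecoderLayer(d_model, n_heads, d_ff, dropout, rng)
            for _ in range(n_decoder_layers)
        ]
        self.pos_table = sinusoidal_positional_encoding(max_len, d_model)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        _, t, _ = x.shape
        x = x + self.pos_table[:t, :]
        memory = x
        for layer in self.encoder_layers:
            memory = layer(memory, training)
        out = x
        for layer in self.decoder_layers:
            out = layer(out, memory, training)
        return out


class RMSProp:
    """RMSProp with exponentially weighted squared-gradient normalisation."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.square_avg = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, sq in zip(self.params, self.square_avg):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
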