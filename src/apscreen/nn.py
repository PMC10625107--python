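"""Minimal numpy neural-network layers with explicit backpropagation.

Only what the transformer regression network needs: token embedding,
sinusoidal positional encoding, multi-head self-attention, layer/batch
normalization, dense layers, leaky-rectifier activations and dropout.
Every layer implements ``forward(x, train)`` and ``backward(dout)``; the
backward pass consumes caches stored by the preceding forward call.
Gradients are averaged over the batch by the loss, so a plain SGD step is
``p -= lr * p.grad``.

All layers are float-dtype agnostic (float32 for speed in training,
float64 for finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays defining the layer's full state (params + buffers)."""
        return [p.value for p in self.params()]

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator, dtype):
        scale = 1.0 / np.sqrt(dim)
        self.W = Param((rng.standard_normal((vocab_size, dim)) * scale).astype(dtype))
        self._ids = None

    def params(self):
        return [self.W]

    def forward(self, ids, train):
        self._ids = ids
        return self.W.value[ids]

    def backward(self, dout):
        # scatter-add via one-hot matmul (faster than np.add.at for a
        # small vocabulary)
        flat_ids = self._ids.reshape(-1)
        onehot = np.zeros((flat_ids.size, self.W.value.shape[0]), dtype=dout.dtype)
        onehot[np.arange(flat_ids.size), flat_ids] = 1.0
        self.W.grad += onehot.T @ dout.reshape(flat_ids.size, -1)
        return None  # token ids carry no gradient


class PositionalEncoding(Layer):
    """Fixed sinusoidal position encoding added to the embeddings."""

    def __init__(self, max_len: int, dim: int, dtype):
        pos = np.arange(max_len)[:, None]
        i = np.arange(dim)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.pe = pe.astype(dtype)

    def forward(self, x, train):
        return x + self.pe[: x.shape[1]]

    def backward(self, dout):
        return dout


class Dense(Layer):
    """Affine map on the last axis (supports any leading dimensions)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype):
        self.W = Param(_glorot(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        # collapse leading axes so BLAS sees one large GEMM
        self._x2 = x.reshape(-1, x.shape[-1])
        self._lead = x.shape[:-1]
        out = self._x2 @ self.W.value + self.b.value
        return out.reshape(*self._lead, -1)

    def backward(self, dout):
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += self._x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return (d2 @ self.W.value.T).reshape(*self._lead, -1)


class LayerNorm(Layer):
    def __init__(self, dim: int, dtype, eps: float = 1e-5):
        self.g = Param(np.ones(dim, dtype=dtype))
        self.b = Param(np.zeros(dim, dtype=dtype))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.g, self.b]

    def forward(self, x, train):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g.value * xhat + self.b.value

    def backward(self, dout):
        xhat, inv = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.g.grad += (dout * xhat).sum(axis=axes)
        self.b.grad += dout.sum(axis=axes)
        dxhat = dout * self.g.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class MultiHeadSelfAttention(Layer):
    def __init__(self, dim: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator, dtype):
        inner = n_heads * head_dim
        self.h, self.dk = n_heads, head_dim
        self.Wq = Dense(dim, inner, rng, dtype)
        self.Wk = Dense(dim, inner, rng, dtype)
        self.Wv = Dense(dim, inner, rng, dtype)
        self.Wo = Dense(inner, dim, rng, dtype)
        self._cache = None

    def params(self):
        return (self.Wq.params() + self.Wk.params() + self.Wv.params()
                + self.Wo.params())

    def _split(self, x):
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, L, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dk)

    def forward(self, x, train):
        q = self._split(self.Wq.forward(x, train))
        k = self._split(self.Wk.forward(x, train))
        v = self._split(self.Wv.forward(x, train))
        scale = 1.0 / np.sqrt(self.dk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        att = np.exp(scores)
        att /= att.sum(axis=-1, keepdims=True)
        ctx = att @ v
        self._cache = (q, k, v, att, scale)
        return self.Wo.forward(self._merge(ctx), train)

    def backward(self, dout):
        q, k, v, att, scale = self._cache
        dctx = self._split(self.Wo.backward(dout))
        datt = dctx @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dctx
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dq = (dscores @ k) * scale
        dk_ = (dscores.transpose(0, 1, 3, 2) @ q) * scale
        dx = self.Wq.backward(self._merge(dq))
        dx += self.Wk.backward(self._merge(dk_))
        dx += self.Wv.backward(self._merge(dv))
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class TransformerBlock(Layer):
    """Post-norm encoder block: LN(x + MHA(x)) then LN(y + FFN(y))."""

    def __init__(self, dim: int, n_heads: int, head_dim: int, ffn_dim: int,
                 rng: np.random.Generator, dtype):
        self.att = MultiHeadSelfAttention(dim, n_heads, head_dim, rng, dtype)
        self.ln1 = LayerNorm(dim, dtype)
        self.ffn1 = Dense(dim, ffn_dim, rng, dtype)
        self.act = ReLU()
        self.ffn2 = Dense(ffn_dim, dim, rng, dtype)
        self.ln2 = LayerNorm(dim, dtype)

    def params(self):
        return (self.att.params() + self.ln1.params() + self.ffn1.params()
                + self.ffn2.params() + self.ln2.params())

    def forward(self, x, train):
        y = self.ln1.forward(x + self.att.forward(x, train), train)
        f = self.ffn2.forward(
            self.act.forward(self.ffn1.forward(y, train), train), train
        )
        return self.ln2.forward(y + f, train)

    def backward(self, dout):
        dz = self.ln2.backward(dout)
        dy = dz + self.ffn1.backward(self.act.backward(self.ffn2.backward(dz)))
        dx = self.ln1.backward(dy)
        return dx + self.att.backward(dx)


class BatchNorm1d(Layer):
    """Batch normalization over axis 0 of a (batch, features) input."""

    def __init__(self, dim: int, dtype, momentum: float = 0.1, eps: float = 1e-5):
        self.g = Param(np.ones(dim, dtype=dtype))
        self.b = Param(np.zeros(dim, dtype=dtype))
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.g, self.b]

    def state_arrays(self):
        return [self.g.value, self.b.value, self.running_mean, self.running_var]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train)
        return self.g.value * xhat + self.b.value

    def backward(self, dout):
        xhat, inv, was_train = self._cache
        self.g.grad += (dout * xhat).sum(axis=0)
        self.b.grad += dout.sum(axis=0)
        dxhat = dout * self.g.value
        if not was_train:
            return dxhat * inv
        m1 = dxhat.mean(axis=0)
        m2 = (dxhat * xhat).mean(axis=0)
        return inv * (dxhat - m1 - xhat * m2)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class MeanPool(Layer):
    """Mean over the sequence axis of a (batch, length, dim) input."""

    def forward(self, x, train):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._L, axis=1) / self._L


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def sgd_step(params: list[Param], lr: float) -> None:
    for p in params:
        p.value -= lr * p.grad
        p.zero_grad()


def snapshot(state: list[np.ndarray]) -> list[np.ndarray]:
    return [a.copy() for a in state]


def restore(state: list[np.ndarray], saved: list[np.ndarray]) -> None:
    for a, s in zip(state, saved):
        a[...] = s
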