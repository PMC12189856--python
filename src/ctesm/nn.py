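"""Minimal neural-network layers with explicit forward/backward passes.

The hybrid classifier is small (order 10^5 parameters) and trains on a CPU
in seconds, so the layers are written directly in numpy with hand-derived
gradients rather than through an autodiff framework. Every layer follows
the same protocol: ``forward(x, training)`` caches what ``backward(dout)``
needs; parameters are ``Param`` objects whose gradients are accumulated by
``backward`` and consumed by :class:`Adam`.

Conventions: batch-first arrays; sequences are ``(batch, time, dim)``;
convolutions are 1-D 'valid' along the sequence axis; layer normalization
is non-affine (plain standardization over the feature axis); the LSTM uses
gate order input, forget, cell, output with forget-gate bias initialized
to 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "BatchNorm",
    "Conv1d",
    "Dense",
    "Dropout",
    "LSTM",
    "LayerNorm",
    "MaxPool1d",
    "MultiHeadAttention",
    "Param",
    "ReLU",
    "attention",
    "glorot_uniform",
    "softmax",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(a: np.ndarray, da: np.ndarray, axis: int = -1) -> np.ndarray:
    # a = softmax(z); returns dL/dz given dL/da
    return a * (da - (da * a).sum(axis=axis, keepdims=True))


def attention(q: np.ndarray, k: np.ndarray, v: np.ndarray, d_k: int) -> np.ndarray:
    """Scaled dot-product attention softmax(QK^T/sqrt(d_k))V.

    Accepts ``(..., T, d)`` stacks; the softmax is over keys. Stateless
    helper used by :class:`MultiHeadAttention` and directly testable.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    return softmax(scores, axis=-1) @ v


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map over the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Conv1d(Layer):
    """1-D 'valid' convolution along axis 1 of a (B, L, C_in) array."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        fan_in = in_ch * kernel_size
        self.W = Param(glorot_uniform(rng, (kernel_size, in_ch, out_ch), fan_in, out_ch))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        b, L, cin = x.shape
        lout = L - self.k + 1
        if lout < 1:
            raise ValueError(f"sequence length {L} shorter than kernel {self.k}")
        self._x = x
        out = np.zeros((b, lout, self.W.value.shape[2]))
        for ki in range(self.k):
            out += x[:, ki : ki + lout, :] @ self.W.value[ki]
        return out + self.b.value

    def backward(self, dout):
        x = self._x
        b, L, cin = x.shape
        lout = dout.shape[1]
        dx = np.zeros_like(x)
        for ki in range(self.k):
            seg = x[:, ki : ki + lout, :].reshape(-1, cin)
            self.W.grad[ki] += seg.T @ dout.reshape(-1, dout.shape[-1])
            dx[:, ki : ki + lout, :] += dout @ self.W.value[ki].T
        self.b.grad += dout.sum(axis=(0, 1))
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""

    def __init__(self, pool_size: int):
        self.p = pool_size

    def forward(self, x, training=False):
        b, L, c = x.shape
        lout = L // self.p
        xt = x[:, : lout * self.p, :].reshape(b, lout, self.p, c)
        self._argmax = xt.argmax(axis=2)
        self._shape = x.shape
        return xt.max(axis=2)

    def backward(self, dout):
        b, lout, c = dout.shape
        dx = np.zeros(self._shape)
        bi, li, ci = np.meshgrid(
            np.arange(b), np.arange(lout), np.arange(c), indexing="ij"
        )
        dxt = dx[:, : lout * self.p, :].reshape(b, lout, self.p, c)
        dxt[bi, li, self._argmax, ci] = dout
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (per-feature)."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        self._training = training
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not self._training:
            return dxhat * self._inv_sd
        n = self._n
        return (
            self._inv_sd
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        )


class LayerNorm(Layer):
    """Non-affine layer normalization: (x − μ)/σ over the last axis."""

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._y = (x - mu) * self._inv_sd
        return self._y

    def backward(self, dout):
        y = self._y
        mean_d = dout.mean(axis=-1, keepdims=True)
        mean_dy = (dout * y).mean(axis=-1, keepdims=True)
        return self._inv_sd * (dout - mean_d - y * mean_dy)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MultiHeadAttention(Layer):
    """Multi-head scaled dot-product self-attention.

    Parallel heads project the (B, T, D) input to per-head queries, keys and
    values of width d_k, attend with softmax(QK^T/sqrt(d_k))V, then the head
    outputs are concatenated and linearly projected back to D.
    """

    def __init__(self, d_model: int, n_heads: int, d_k: int, rng: np.random.Generator):
        if d_k <= 0:
            raise ValueError("d_k must be positive")
        h = n_heads * d_k
        self.n_heads, self.d_k, self.d_model = n_heads, d_k, d_model
        self.Wq = Param(glorot_uniform(rng, (d_model, h), d_model, h))
        self.Wk = Param(glorot_uniform(rng, (d_model, h), d_model, h))
        self.Wv = Param(glorot_uniform(rng, (d_model, h), d_model, h))
        self.Wo = Param(glorot_uniform(rng, (h, d_model), h, d_model))

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def _split(self, z, B, T):
        # (B, T, H*dk) -> (B, H, T, dk)
        return z.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x, training=False):
        B, T, D = x.shape
        self._x = x
        q = self._split(x @ self.Wq.value, B, T)
        k = self._split(x @ self.Wk.value, B, T)
        v = self._split(x @ self.Wv.value, B, T)
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.d_k)
        a = softmax(scores, axis=-1)
        heads = a @ v  # (B, H, T, dk)
        concat = heads.transpose(0, 2, 1, 3).reshape(B, T, -1)
        self._cache = (q, k, v, a, concat)
        return concat @ self.Wo.value

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """(B, H, T, T) softmax attention maps for a given input (no cache)."""
        B, T, D = x.shape
        q = self._split(x @ self.Wq.value, B, T)
        k = self._split(x @ self.Wk.value, B, T)
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.d_k)
        return softmax(scores, axis=-1)

    def backward(self, dout):
        x = self._x
        B, T, D = x.shape
        q, k, v, a, concat = self._cache
        self.Wo.grad += concat.reshape(-1, concat.shape[-1]).T @ dout.reshape(-1, D)
        dconcat = dout @ self.Wo.value.T
        dheads = dconcat.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)
        da = dheads @ np.swapaxes(v, -1, -2)
        dv = np.swapaxes(a, -1, -2) @ dheads
        dscores = _softmax_backward(a, da, axis=-1) / np.sqrt(self.d_k)
        dq = dscores @ k
        dk = np.swapaxes(dscores, -1, -2) @ q
        dx = np.zeros_like(x)
        for dz, W in ((dq, self.Wq), (dk, self.Wk), (dv, self.Wv)):
            dz_flat = dz.transpose(0, 2, 1, 3).reshape(B * T, -1)
            W.grad += x.reshape(B * T, D).T @ dz_flat
            dx += (dz_flat @ W.value.T).reshape(B, T, D)
        return dx


class LSTM(Layer):
    """Single-layer LSTM; returns the final hidden state h_T.

    Gates (input i, forget f, cell candidate g, output o) are computed from
    the concatenation [h_{t-1}, x_t]; initial states are zero; the forget
    bias starts at 1 (standard practice for gradient flow).
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        fan_in = d_in + units
        self.W = Param(glorot_uniform(rng, (fan_in, 4 * units), fan_in, 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(T):
            zcat = np.concatenate([h, x[:, t, :]], axis=1)
            gates = zcat @ self.W.value + self.b.value
            i = self._sigmoid(gates[:, :H])
            f = self._sigmoid(gates[:, H : 2 * H])
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = self._sigmoid(gates[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            self._cache.append((zcat, i, f, g, o, c_prev, tanh_c))
        return h

    def backward(self, dh_T):
        x = self._x
        B, T, D = x.shape
        H = self.units
        dx = np.zeros_like(x)
        dh = dh_T.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            zcat, i, f, g, o, c_prev, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.W.grad += zcat.T @ dgates
            self.b.grad += dgates.sum(axis=0)
            dzcat = dgates @ self.W.value.T
            dh = dzcat[:, :H]
            dx[:, t, :] = dzcat[:, H:]
            dc = dc * f
        return dx


class Adam:
    """Adam optimizer (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
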