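"""Minimal NumPy neural-network core with explicit backpropagation.

Float32 throughout; every source of randomness (initialisation, shuffling,
dropout) flows from a single seeded Generator owned by the caller, so
training runs are bit-reproducible on a fixed BLAS.  Implements exactly
what the package's heads need: dense layers, ReLU, dropout, batch
normalization, scaled dot-product self-attention over short concept
sequences, sigmoid binary cross-entropy, and Adam.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Forward/backward unit with named parameters and matching gradients."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)  # He init, ReLU-friendly
        self.params = {
            "W": (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE),
            "b": np.zeros(n_out, dtype=DTYPE),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {
            "W": self._x.T @ dout,
            "b": dout.sum(axis=0),
        }
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self._rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(n_features, dtype=DTYPE),
            "beta": np.zeros(n_features, dtype=DTYPE),
        }
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        n = dout.shape[0]
        xhat, std = self._xhat, self._std
        self.grads = {
            "gamma": (dout * xhat).sum(axis=0),
            "beta": dout.sum(axis=0),
        }
        dxhat = dout * self.params["gamma"]
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class SelfAttention(Layer):
    """Scaled dot-product self-attention over a short concept sequence.

    Input (B, T, D); learned query/key/value projections (no output
    projection, so with T=1 the layer reduces to the value projection of
    its input).  Attention weights of the last forward pass are kept in
    ``last_attention`` with shape (B, heads, T, T); every row is a simplex.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        scale = math.sqrt(1.0 / dim)
        self.params = {
            name: (rng.standard_normal((dim, dim)) * scale).astype(DTYPE)
            for name in ("Wq", "Wk", "Wv")
        }
        self.n_heads = n_heads
        self.dim = dim
        self.last_attention: np.ndarray | None = None

    def _split(self, x):
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, -1).transpose(0, 2, 1, 3)

    def _merge(self, x):
        b, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)

    def forward(self, x, train):
        self._x = x
        q = self._split(x @ self.params["Wq"])
        k = self._split(x @ self.params["Wk"])
        v = self._split(x @ self.params["Wv"])
        dh = q.shape[-1]
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        self._cache = (q, k, v, attn)
        self.last_attention = attn
        return self._merge(attn @ v)

    def backward(self, dout):
        x = self._x
        q, k, v, attn = self._cache
        dh = q.shape[-1]
        do = self._split_like(dout)
        dattn = do @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ do
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds /= math.sqrt(dh)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dq_full = self._merge(dq)
        dk_full = self._merge(dk)
        dv_full = self._merge(dv)
        b, t, d = x.shape
        x2 = x.reshape(-1, d)
        self.grads = {
            "Wq": x2.T @ dq_full.reshape(-1, d),
            "Wk": x2.T @ dk_full.reshape(-1, d),
            "Wv": x2.T @ dv_full.reshape(-1, d),
        }
        return (
            dq_full @ self.params["Wq"].T
            + dk_full @ self.params["Wk"].T
            + dv_full @ self.params["Wv"].T
        )

    def _split_like(self, x):
        return self._split(np.ascontiguousarray(x))


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x.astype(DTYPE, copy=False), train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self.layers for name in l.params]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr
            if isinstance(layer, BatchNorm):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].astype(DTYPE).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].astype(DTYPE).copy()
                layer.running_var = state[f"{i}.running_var"].astype(DTYPE).copy()


# ---------------------------------------------------------------------------
# loss


def bce_with_logits_sum(logits: np.ndarray, labels: np.ndarray,
                        clamp: float = 30.0) -> float:
    """Sum over all elements of sigmoid binary cross-entropy.

    Uses the stable form max(z,0) - z*y + log(1+exp(-|z|)); logits are
    clamped to ±``clamp`` first, bounding each term away from overflow.
    """
    z = np.clip(np.asarray(logits, dtype=np.float64), -clamp, clamp)
    y = np.asarray(labels, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} != labels shape {y.shape}")
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.sum())


def bce_with_logits_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the summed BCE w.r.t. logits: sigmoid(z) - y."""
    z = np.asarray(logits, dtype=np.float64)
    return (1.0 / (1.0 + np.exp(-z)) - labels).astype(DTYPE)


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, (layer, name) in enumerate(model.parameters()):
            key = (id(layer), name)
            self.m[key] = np.zeros_like(layer.params[name])
            self.v[key] = np.zeros_like(layer.params[name])

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(DTYPE)
            if self.weight_decay and name not in ("b", "beta", "gamma"):
                g = g + self.weight_decay * layer.params[name]
            key = (id(layer), name)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            layer.params[name] = (
                layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(DTYPE)
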