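"""Minimal NumPy neural-network layer library with reverse-mode gradients.

Provides exactly the layers the three sequence-regression architectures
need: dense, 1-D convolution (same padding, im2col), max pooling, ReLU,
dropout, batch normalization, LSTM (full backpropagation through time), and
a repeat-vector operator, composed by a :class:`Sequential` container.

Conventions: batches are leading; sequence tensors are (batch, time,
features); vector tensors are (batch, features).  All parameters are float64
NumPy arrays initialized from an explicit ``numpy.random.Generator`` so model
construction is deterministic under a seed.  Dropout draws from the rng
passed to ``forward`` at training time.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "BatchNorm",
    "Conv1D",
    "MaxPool1D",
    "LSTM",
    "RepeatVector",
    "TakeLast",
    "Sequential",
    "glorot_normal",
]


def glorot_normal(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: trainable ``params``/``grads`` and optional buffers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, grad_out):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias_init: float = 0.0):
        super().__init__()
        self.params["W"] = glorot_normal(rng, n_in, n_out, (n_in, n_out))
        self.params["b"] = np.full(n_out, float(bias_init))

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad_out):
        self.grads["W"] = self._x.T @ grad_out
        self.grads["b"] = grad_out.sum(axis=0)
        return grad_out @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidArgumentError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise InvalidArgumentError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (batch, features) input."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.buffers["running_mean"] = np.zeros(n_features)
        self.buffers["running_var"] = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mean
        self._xhat = self._xc * self._istd
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad_out):
        self.grads["gamma"] = (grad_out * self._xhat).sum(axis=0)
        self.grads["beta"] = grad_out.sum(axis=0)
        dxhat = grad_out * self.params["gamma"]
        if not self._training:
            return dxhat * self._istd
        n = grad_out.shape[0]
        # standard batch-norm gradient with batch statistics
        dvar = (dxhat * self._xc).sum(axis=0) * (-0.5) * self._istd**3
        dmean = -(dxhat * self._istd).sum(axis=0) + dvar * (-2.0 / n) * self._xc.sum(axis=0)
        return dxhat * self._istd + dvar * 2.0 * self._xc / n + dmean / n


class Conv1D(Layer):
    """1-D convolution with odd kernel and same padding on (B, T, C) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise InvalidArgumentError("kernel width must be odd")
        self.kernel = kernel
        self.c_in = c_in
        fan_in, fan_out = kernel * c_in, c_out
        self.params["W"] = glorot_normal(rng, fan_in, fan_out, (kernel * c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def _im2col(self, xpad, t):
        b, _, c = xpad.shape
        k = self.kernel
        cols = np.empty((b, t, k * c), dtype=xpad.dtype)
        for i in range(k):
            cols[:, :, i * c : (i + 1) * c] = xpad[:, i : i + t, :]
        return cols

    def forward(self, x, training=False, rng=None):
        b, t, c = x.shape
        pad = (self.kernel - 1) // 2
        xpad = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._cols = self._im2col(xpad, t)
        self._in_shape = (b, t, c)
        out = self._cols.reshape(b * t, -1) @ self.params["W"] + self.params["b"]
        return out.reshape(b, t, -1)

    def backward(self, grad_out):
        b, t, c = self._in_shape
        k, pad = self.kernel, (self.kernel - 1) // 2
        g = grad_out.reshape(b * t, -1)
        self.grads["W"] = self._cols.reshape(b * t, -1).T @ g
        self.grads["b"] = g.sum(axis=0)
        gcols = (g @ self.params["W"].T).reshape(b, t, k * c)
        gxpad = np.zeros((b, t + 2 * pad, c), dtype=grad_out.dtype)
        for i in range(k):
            gxpad[:, i : i + t, :] += gcols[:, :, i * c : (i + 1) * c]
        return gxpad[:, pad : pad + t, :]


class MaxPool1D(Layer):
    """Non-overlapping max pool along time; a trailing odd sample is dropped."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def forward(self, x, training=False, rng=None):
        b, t, c = x.shape
        t_out = t // self.width
        xr = x[:, : t_out * self.width, :].reshape(b, t_out, self.width, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = (b, t, c)
        return xr.max(axis=2)

    def backward(self, grad_out):
        b, t, c = self._in_shape
        t_out = t // self.width
        gxr = np.zeros((b, t_out, self.width, c), dtype=grad_out.dtype)
        bi, ti, ci = np.ogrid[:b, :t_out, :c]
        gxr[bi, ti, self._arg, ci] = grad_out
        gx = np.zeros((b, t, c), dtype=grad_out.dtype)
        gx[:, : t_out * self.width, :] = gxr.reshape(b, t_out * self.width, c)
        return gx


class LSTM(Layer):
    """Single LSTM layer with full backpropagation through time.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1.  ``return_sequences`` selects between
    emitting the hidden state at every step or only at the last.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        super().__init__()
        h = n_hidden
        self.n_hidden = h
        self.return_sequences = return_sequences
        self.params["W"] = glorot_normal(rng, n_in, h, (n_in, 4 * h))
        self.params["U"] = glorot_normal(rng, h, h, (h, 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params["b"] = b

    def forward(self, x, training=False, rng=None):
        b, t, _ = x.shape
        h = self.n_hidden
        W, U, bias = self.params["W"], self.params["U"], self.params["b"]
        hs = np.zeros((b, t + 1, h))
        cs = np.zeros((b, t + 1, h))
        gates = np.empty((b, t, 4 * h))
        tanh_c = np.empty((b, t, h))
        for step in range(t):
            z = x[:, step, :] @ W + hs[:, step, :] @ U + bias
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c = f * cs[:, step, :] + i * g
            tc = np.tanh(c)
            cs[:, step + 1, :] = c
            hs[:, step + 1, :] = o * tc
            gates[:, step, :] = np.concatenate([i, f, g, o], axis=1)
            tanh_c[:, step, :] = tc
        self._cache = (x, hs, cs, gates, tanh_c)
        if self.return_sequences:
            return hs[:, 1:, :]
        return hs[:, -1, :]

    def backward(self, grad_out):
        x, hs, cs, gates, tanh_c = self._cache
        b, t, n_in = x.shape
        h = self.n_hidden
        W, U = self.params["W"], self.params["U"]
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros_like(self.params["b"])
        gx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        if self.return_sequences:
            dh_seq = grad_out
        else:
            dh_seq = np.zeros((b, t, h))
            dh_seq[:, -1, :] = grad_out
        for step in range(t - 1, -1, -1):
            i = gates[:, step, :h]
            f = gates[:, step, h : 2 * h]
            g = gates[:, step, 2 * h : 3 * h]
            o = gates[:, step, 3 * h :]
            tc = tanh_c[:, step, :]
            dh = dh_seq[:, step, :] + dh_next
            dc = dc_next + dh * o * (1 - tc**2)
            di = dc * g * i * (1 - i)
            df = dc * cs[:, step, :] * f * (1 - f)
            dg = dc * i * (1 - g**2)
            do = dh * tc * o * (1 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            gW += x[:, step, :].T @ dz
            gU += hs[:, step, :].T @ dz
            gb += dz.sum(axis=0)
            gx[:, step, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"], self.grads["U"], self.grads["b"] = gW, gU, gb
        return gx


class RepeatVector(Layer):
    """(B, F) -> (B, n, F) by repetition; gradient sums over time."""

    def __init__(self, n: int):
        super().__init__()
        self.n = n

    def forward(self, x, training=False, rng=None):
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, grad_out):
        return grad_out.sum(axis=1)


class TakeLast(Layer):
    """(B, T, F) -> (B, F): the features at the final time step."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, grad_out):
        gx = np.zeros(self._shape, dtype=grad_out.dtype)
        gx[:, -1, :] = grad_out
        return gx


class Sequential:
    """Ordered layer stack with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    __call__ = forward

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        """Flat list of (layer_index, name, array) for all trainable tensors."""
        out = []
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out.append((i, name, p))
        return out

    def gradients(self):
        return [self.layers[i].grads[name] for i, name, _ in self.parameters()]

    def get_weights(self) -> list[np.ndarray]:
        """Copies of all parameters and buffers, in a stable order."""
        out = [p.copy() for _, _, p in self.parameters()]
        for layer in self.layers:
            out.extend(v.copy() for v in layer.buffers.values())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        # in-place copy so references held by an optimizer stay valid
        idx = 0
        for i, name, p in self.parameters():
            p[...] = weights[idx]
            idx += 1
        for layer in self.layers:
            for name in layer.buffers:
                layer.buffers[name][...] = weights[idx]
                idx += 1
        if idx != len(weights):
            raise InvalidArgumentError("weight list does not match the model")
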