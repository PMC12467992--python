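"""Minimal NumPy neural-network engine for the bLSTM EEG classifier.

Implements exactly the layers the classifier needs — LSTM (with full
backpropagation through time), bidirectional wrapper, dense, ReLU, inverted
dropout — plus softmax cross-entropy and an Adam optimizer.  Everything is
seeded and batch-vectorized; time steps are looped.

Shapes: sequence tensors are ``(batch, time, features)``; flat tensors are
``(batch, features)``.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: forward caches what backward needs; params exposes weights+grads."""

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def params(self):
        return {}

    def grads(self):
        return {}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.name = name
        self.W = glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTM(Layer):
    """Single-direction LSTM with BPTT.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1.  ``return_sequences`` selects the full
    ``(B, T, H)`` output versus the final hidden state ``(B, H)``;
    ``backwards`` processes the sequence reversed (output is re-reversed when
    sequences are returned).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True, backwards: bool = False,
                 name: str = "lstm"):
        self.name = name
        self.hidden = hidden
        self.return_sequences = return_sequences
        self.backwards = backwards
        h4 = 4 * hidden
        self.Wx = glorot(rng, (n_in, h4))
        self.Wh = glorot(rng, (hidden, h4))
        self.b = np.zeros(h4)
        self.b[hidden:2 * hidden] = 1.0  # forget bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        if self.backwards:
            x = x[:, ::-1]
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._hs = hs
        if self.return_sequences:
            return hs[:, ::-1] if self.backwards else hs
        return hs[:, -1]

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        H = self.hidden
        if self.return_sequences:
            dH = dy[:, ::-1] if self.backwards else dy
        else:
            dH = None
        self.dWx[:] = 0.0
        self.dWh[:] = 0.0
        self.db[:] = 0.0
        dx = np.empty_like(x)
        dh_next = dy.copy() if dH is None else np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dh_next if dH is None and t == T - 1 else (
                dh_next + (dH[:, t] if dH is not None else 0.0))
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.dWx += x[:, t].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        if self.backwards:
            dx = dx[:, ::-1]
        return dx

    def params(self):
        return {f"{self.name}/Wx": self.Wx, f"{self.name}/Wh": self.Wh,
                f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/Wx": self.dWx, f"{self.name}/Wh": self.dWh,
                f"{self.name}/b": self.db}


class BiLSTM(Layer):
    """Forward + backward LSTM; outputs are concatenated on the feature axis."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True, name: str = "bilstm"):
        self.fwd = LSTM(n_in, hidden, rng, return_sequences=return_sequences,
                        backwards=False, name=f"{name}/fwd")
        self.bwd = LSTM(n_in, hidden, rng, return_sequences=return_sequences,
                        backwards=True, name=f"{name}/bwd")
        self.hidden = hidden
        self.return_sequences = return_sequences

    def forward(self, x, train=False, rng=None):
        yf = self.fwd.forward(x, train, rng)
        yb = self.bwd.forward(x, train, rng)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        H = self.hidden
        dxf = self.fwd.backward(dy[..., :H])
        dxb = self.bwd.backward(dy[..., H:])
        return dxf + dxb

    def params(self):
        return {**self.fwd.params(), **self.bwd.params()}

    def grads(self):
        return {**self.fwd.grads(), **self.bwd.grads()}


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs, y_onehot, eps: float = 1e-12):
    return float(-np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1)))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 0.03, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t)
                                                + self.eps)


class Sequential:
    """Plain layer stack with softmax-cross-entropy training step."""

    def __init__(self, layers, seed: int = 0):
        self.layers = layers
        self._rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=self._rng)
        return x

    def predict_proba(self, x, batch_size: int = 64):
        out = []
        for k in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[k:k + batch_size], train=False)))
        return np.concatenate(out)

    def params(self):
        d = {}
        for layer in self.layers:
            d.update(layer.params())
        return d

    def grads(self):
        d = {}
        for layer in self.layers:
            d.update(layer.grads())
        return d

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params().values()))

    def train_step(self, x, y_onehot, optimizer: Adam,
                   clip_norm: float | None = 5.0) -> float:
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y_onehot)
        dlogits = (probs - y_onehot) / x.shape[0]
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        grads = self.grads()
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                for g in grads.values():
                    g *= scale
        optimizer.step(self.params(), grads)
        return loss


def build_concnet(n_channels: int = 64, lstm_units: int = 24,
                  dropout: float = 0.32, fc_hidden: int = 8,
                  n_classes: int = 2, seed: int = 0) -> Sequential:
    """The ConcNet stack: two bidirectional LSTM layers (sequence-to-sequence,
    then final-state), each followed by dropout, a ReLU dense layer with
    dropout, and the softmax output layer (softmax applied in the loss /
    ``predict_proba``).
    """
    rng = np.random.default_rng(seed)
    layers = [
        BiLSTM(n_channels, lstm_units, rng, return_sequences=True,
               name="bilstm1"),
        Dropout(dropout),
        BiLSTM(2 * lstm_units, lstm_units, rng, return_sequences=False,
               name="bilstm2"),
        Dropout(dropout),
        Dense(2 * lstm_units, fc_hidden, rng, name="fc1"),
        ReLU(),
        Dropout(dropout),
        Dense(fc_hidden, n_classes, rng, name="fc2"),
    ]
    return Sequential(layers, seed=seed)
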