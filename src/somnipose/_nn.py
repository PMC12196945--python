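"""Minimal numpy neural-network engine used by the posture classifier.

Implements exactly the building blocks the classifier needs — temporal 1-D
convolution, ReLU, global max/average pooling, LSTM and bidirectional LSTM
cells, a dense layer, softmax cross-entropy and the Adam optimizer — with
hand-derived backward passes.  Everything is plain float64 numpy, seeded
through ``numpy.random.Generator``, so training is bitwise-repeatable for a
fixed seed.

Array convention: sequence batches are ``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1d",
    "ReLU",
    "GlobalMaxPool1d",
    "GlobalAvgPool1d",
    "LSTM",
    "BiLSTM",
    "Adam",
    "SGD",
    "softmax",
    "cross_entropy",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: layers expose aligned ``params`` and ``grads`` lists."""

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Conv1d(Layer):
    """1-D convolution over the time axis with 'same' zero padding.

    Kernel size must be odd.  Input (B, T, C_in) -> output (B, T, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel * c_in
        self.W = _glorot(rng, fan_in, c_out, (fan_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        p = self.kernel // 2
        xp = np.zeros((B, T + 2 * p, C))
        xp[:, p : p + T, :] = x
        return np.concatenate(
            [xp[:, i : i + T, :] for i in range(self.kernel)], axis=2
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"window of {x.shape[1]} time steps is too short for a "
                f"kernel of size {self.kernel}"
            )
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        return self._cols @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        p = self.kernel // 2
        cols2d = self._cols.reshape(-1, self.kernel * C)
        self.dW += cols2d.T @ g.reshape(-1, self.c_out)
        self.db += g.sum(axis=(0, 1))
        dcols = g @ self.W.T  # (B, T, kernel*C)
        dxp = np.zeros((B, T + 2 * p, C))
        for i in range(self.kernel):
            dxp[:, i : i + T, :] += dcols[:, :, i * C : (i + 1) * C]
        return dxp[:, p : p + T, :]

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class GlobalMaxPool1d(Layer):
    """Max over the time axis: (B, T, C) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._arg[:, None, :], g[:, None, :], axis=1)
        return dx


class GlobalAvgPool1d(Layer):
    """Mean over the time axis: (B, T, C) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, None, :], self._T, axis=1) / self._T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Unidirectional LSTM returning the final hidden state.

    Single weight matrix over [x_t, h_{t-1}] with gate order (input, forget,
    cell, output); forget-gate bias initialized to 1 as is customary.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.hidden = hidden
        self.W = _glorot(rng, n_in + hidden, 4 * hidden, (n_in + hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ self.W + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._cache.append((xh, i, f, g, o, c_prev, tc))
        return h

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        B, T, C = self._x.shape
        H = self.hidden
        dx = np.zeros_like(self._x)
        dh = dh_final.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dW += xh.T @ dz
            self.db += dz.sum(axis=0)
            dxh = dz @ self.W.T
            dx[:, t, :] = dxh[:, :C]
            dh = dxh[:, C:]
            dc = dc * f
        return dx

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and time-reversed cells, features concatenated.

    Output is ``[h_forward, h_backward]`` of width 2*hidden, where each term
    is the final hidden state of its direction (i.e. each has read the whole
    window).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, hidden, rng)
        self.bwd = LSTM(n_in, hidden, rng)
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        H = self.hidden
        dxf = self.fwd.backward(g[:, :H])
        dxb = self.bwd.backward(g[:, H:])
        return dxf + dxb[:, ::-1, :]

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    def gradients(self):
        return self.fwd.gradients() + self.bwd.gradients()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    B = logits.shape[0]
    loss = float(-np.log(p[np.arange(B), y] + 1e-300).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class SGD:
    def __init__(self, params, grads, lr: float = 1e-2):
        self.params = params
        self.grads = grads
        self.lr = lr

    def step(self) -> None:
        for p, g in zip(self.params, self.grads):
            p -= self.lr * g

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
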