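"""Compact neural-network core: layers, backprop, Adam.

Implements exactly the two architectures the package needs — a stacked
long short-term memory (LSTM) sequence classifier and a 1-D convolutional
classifier — as plain numpy with hand-written gradients. Layers follow the
usual conventions (LSTM gate order i, f, g, o; forget-gate bias initialized
to 1; 'same' convolution padding). float32 by default; tests run the layers
in float64 for numerical gradient checking.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng, shape, dtype):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Dense:
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        self.W = _glorot(rng, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = {"W": self.W, "b": self.b}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LSTM:
    """Single LSTM layer over (N, T, n_in) returning the full hidden sequence.

    The input projection for all time steps is computed in one matrix
    product; only the recurrent product runs per step.
    """

    def __init__(self, n_in, n_hidden, rng, dtype=np.float32):
        H = n_hidden
        self.H = H
        self.Wx = _glorot(rng, (n_in, 4 * H), dtype)
        self.Wh = _glorot(rng, (H, 4 * H), dtype)
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.params = {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        N, T, _ = x.shape
        H = self.H
        dtype = self.Wx.dtype
        xp = x.reshape(N * T, -1) @ self.Wx  # all input projections at once
        xp = xp.reshape(N, T, 4 * H) + self.b
        h = np.zeros((N, H), dtype=dtype)
        c = np.zeros((N, H), dtype=dtype)
        self._x = x
        self._gates = np.empty((N, T, 4 * H), dtype=dtype)
        self._c = np.empty((N, T, H), dtype=dtype)
        self._h = np.empty((N, T, H), dtype=dtype)
        for t in range(T):
            z = xp[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            self._gates[:, t, :H] = i
            self._gates[:, t, H : 2 * H] = f
            self._gates[:, t, 2 * H : 3 * H] = g
            self._gates[:, t, 3 * H :] = o
            self._c[:, t] = c
            self._h[:, t] = h
        return self._h

    def backward(self, dh_seq):
        x, gates, cs, hs = self._x, self._gates, self._c, self._h
        N, T, _ = x.shape
        H = self.H
        dtype = self.Wx.dtype
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dz_all = np.empty((N, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((N, H), dtype=dtype)
        dc_next = np.zeros((N, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c = cs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((N, H), dtype=dtype)
            dh = dh_seq[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dz_all[:, t] = dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ self.Wh.T
        dz_flat = dz_all.reshape(N * T, 4 * H)
        self.grads["Wx"][...] = x.reshape(N * T, -1).T @ dz_flat
        self.grads["Wh"][...] = dWh
        self.grads["b"][...] = db
        dx = dz_flat @ self.Wx.T
        return dx.reshape(N, T, -1)


class Conv1d:
    """1-D convolution with 'same' zero padding, channels-first (N, C, L)."""

    def __init__(self, n_in, n_out, kernel, rng, dtype=np.float32):
        self.K = kernel
        limit = np.sqrt(6.0 / (n_in * kernel + n_out * kernel))
        self.W = rng.uniform(-limit, limit, size=(n_out, n_in, kernel)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = {"W": self.W, "b": self.b}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        N, C, L = x.shape
        K = self.K
        pad = K // 2
        xp = np.zeros((N, C, L + K - 1), dtype=x.dtype)
        xp[:, :, pad : pad + L] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (N,C,L,K)
        self._win = win
        self._in_shape = x.shape
        y = np.tensordot(win, self.W, axes=([1, 3], [1, 2]))  # (N, L, out)
        return np.ascontiguousarray(y.transpose(0, 2, 1)) + self.b[None, :, None]

    def backward(self, dy):
        N, C, L = self._in_shape
        K = self.K
        pad = K // 2
        self.grads["W"][...] = np.tensordot(dy, self._win, axes=([0, 2], [0, 2]))
        self.grads["b"][...] = dy.sum(axis=(0, 2))
        dxp = np.zeros((N, C, L + K - 1), dtype=dy.dtype)
        for k in range(K):
            # dy (N,out,L) x W[:, :, k] (out,C) -> (N,C,L)
            dxp[:, :, k : k + L] += np.einsum("nol,oc->ncl", dy, self.W[:, :, k])
        return dxp[:, :, pad : pad + L]


class MaxPool1d:
    """Non-overlapping max pooling of width 2 (truncates odd lengths)."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x):
        N, C, L = x.shape
        L2 = L // 2
        xr = x[:, :, : 2 * L2].reshape(N, C, L2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        N, C, L = self._shape
        L2 = L // 2
        dxr = np.zeros((N, C, L2, 2), dtype=dy.dtype)
        idx = self._arg
        n, c, l = np.ogrid[:N, :C, :L2]
        dxr[n, c, l, idx] = dy
        dx = np.zeros((N, C, L), dtype=dy.dtype)
        dx[:, :, : 2 * L2] = dxr.reshape(N, C, 2 * L2)
        return dx


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y):
    """Mean multinomial cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers
        ]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
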