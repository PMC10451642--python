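"""Minimal numpy implementation of a 1-D CNN + bidirectional LSTM
regressor.

No deep-learning framework is available in the target environment, so the
network is written directly in numpy with hand-derived backpropagation:
two strided convolution blocks (ReLU + max-pool) encode the two
valve-sound channels, a bidirectional LSTM reads the resulting length-16
feature sequence, and a dense head maps the concatenated final hidden
states of both directions to the regression outputs.  Training is
mini-batch Adam on mean-squared error.  All randomness (initialisation,
shuffling) flows from one seeded generator, so training is bit
reproducible.

Shapes use the convention (batch, channels, length) for convolutions and
(batch, time, features) for the recurrence.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNBiLSTM"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50.0, 50.0)))


class _Conv1d:
    """Strided 1-D convolution with symmetric zero padding."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, stride: int,
                 pad: int):
        self.k, self.stride, self.pad = k, stride, pad
        self.W = _glorot(rng, (c_out, c_in, k), c_in * k, c_out * k)
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        L_out = (L + 2 * self.pad - self.k) // self.stride + 1
        idx = (self.stride * np.arange(L_out)[:, None]
               + np.arange(self.k)[None, :])
        cols = xp[:, :, idx]                      # (B, C, L_out, K)
        self._cache = (cols, x.shape, idx)
        return np.einsum("fck,bclk->bfl", self.W, cols) + self.b[None, :, None]

    def backward(self, dy: np.ndarray):
        cols, xshape, idx = self._cache
        self.dW = np.einsum("bfl,bclk->fck", dy, cols)
        self.db = dy.sum(axis=(0, 2))
        dcols = np.einsum("bfl,fck->bclk", dy, self.W)
        B, C, L = xshape
        dxp = np.zeros((B, C, L + 2 * self.pad))
        np.add.at(dxp, (slice(None), slice(None), idx), dcols)
        return dxp[:, :, self.pad:self.pad + L]

    @property
    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        B, F, L = x.shape
        xr = x.reshape(B, F, L // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, F, L = self._shape
        dx = np.zeros((B, F, L // 2, 2))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        return dx.reshape(B, F, L)


class _LSTM:
    """Single-layer LSTM; returns the final hidden state."""

    def __init__(self, rng, d_in: int, hidden: int):
        self.H = hidden
        self.Wx = _glorot(rng, (d_in, 4 * hidden), d_in, hidden)
        self.Wh = _glorot(rng, (hidden, 4 * hidden), hidden, hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.H
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1,
            )
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class _Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class CNNBiLSTM:
    """Waveform regressor: conv blocks -> Bi-LSTM -> dense head.

    Parameters
    ----------
    n_in_channels : input waveform channels (tricuspid + pulmonary = 2)
    seq_len : fixed resampled waveform length (must be divisible by 16)
    n_out : regression outputs
    conv_filters : filters of the two conv blocks
    lstm_hidden : LSTM width per direction
    """

    def __init__(self, n_in_channels: int = 2, seq_len: int = 256,
                 n_out: int = 3, conv_filters: tuple[int, int] = (16, 32),
                 lstm_hidden: int = 32, kernel: int = 7, seed: int = 0):
        if seq_len % 16:
            raise ValueError("seq_len must be divisible by 16")
        rng = np.random.default_rng(seed)
        f1, f2 = conv_filters
        pad = kernel // 2
        self.conv1 = _Conv1d(rng, n_in_channels, f1, kernel, 2, pad)
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv1d(rng, f1, f2, kernel, 2, pad)
        self.pool2 = _MaxPool2()
        self.lstm_f = _LSTM(rng, f2, lstm_hidden)
        self.lstm_b = _LSTM(rng, f2, lstm_hidden)
        self.head = _Dense(rng, 2 * lstm_hidden, n_out)
        self.rng = rng

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.conv1.forward(x)
        self._m1 = a > 0
        a = self.pool1.forward(a * self._m1)
        a = self.conv2.forward(a)
        self._m2 = a > 0
        a = self.pool2.forward(a * self._m2)
        seq = a.transpose(0, 2, 1)              # (B, T, F)
        hf = self.lstm_f.forward(seq)
        hb = self.lstm_b.forward(seq[:, ::-1])
        return self.head.forward(np.concatenate([hf, hb], axis=1))

    def backward(self, dy: np.ndarray) -> None:
        dh = self.head.backward(dy)
        H = dh.shape[1] // 2
        dseq = self.lstm_f.backward(dh[:, :H])
        dseq = dseq + self.lstm_b.backward(dh[:, H:])[:, ::-1]
        da = self.pool2.backward(dseq.transpose(0, 2, 1))
        da = self.conv2.backward(da * self._m2)
        da = self.pool1.backward(da)
        self.conv1.backward(da * self._m1)

    # -- parameter access --------------------------------------------------

    def _params(self):
        mods = [self.conv1, self.conv2, self.lstm_f, self.lstm_b, self.head]
        names = [("W", "dW"), ("b", "db"), ("Wx", "dWx"), ("Wh", "dWh")]
        out = []
        for m in mods:
            for p, d in names:
                if hasattr(m, p):
                    out.append((m, p, d))
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, epochs: int = 40,
            batch_size: int = 64, lr: float = 1e-3, verbose: bool = False):
        """Adam / MSE training; X (n, C, L), Y (n, n_out), both already
        standardized by the caller."""
        params = self._params()
        mom = [np.zeros_like(getattr(m, p)) for m, p, _ in params]
        vel = [np.zeros_like(getattr(m, p)) for m, p, _ in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            total = 0.0
            for i0 in range(0, n, batch_size):
                idx = order[i0:i0 + batch_size]
                xb, yb = X[idx], Y[idx]
                pred = self.forward(xb)
                err = pred - yb
                loss = float(np.mean(err ** 2))
                total += loss * len(idx)
                self.backward(2.0 * err / err.size)
                step += 1
                for j, (m, p, d) in enumerate(params):
                    g = getattr(m, d)
                    mom[j] = b1 * mom[j] + (1 - b1) * g
                    vel[j] = b2 * vel[j] + (1 - b2) * g ** 2
                    mhat = mom[j] / (1 - b1 ** step)
                    vhat = vel[j] / (1 - b2 ** step)
                    setattr(m, p, getattr(m, p) - lr * mhat / (np.sqrt(vhat) + eps))
            if verbose:
                print(f"epoch {epoch + 1}: mse {total / n:.5f}")
        return self

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [self.forward(X[i:i + batch_size])
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)
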