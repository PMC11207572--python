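"""Minimal numpy layer implementations with explicit backward passes.

Each layer owns its parameter arrays and matching gradient buffers and
implements ``forward(x, training)`` / ``backward(dy)``.  Convolutions use
im2col + GEMM with Keras-style "same" padding (left pad ``(k-1)//2``,
right pad ``k//2``); batch normalization follows the usual momentum
running-statistics scheme; dropout is inverted (scaling at train time).
Everything runs in float32.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base: stateless identity."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


def _sliding(xpad: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Sliding windows of length k along ``axis`` (view, no copy)."""
    return np.lib.stride_tricks.sliding_window_view(xpad, k, axis=axis)


class TemporalConv2D(Layer):
    """(N, H, W, Cin) -> (N, H, W, F); kernel (1, kw), same padding on W.

    Implemented as FFT cross-correlation along W — for the 40-tap temporal
    kernel this avoids the large im2col buffers the GEMM formulation needs.
    Weights are stored as (kw, Cin, F).
    """

    def __init__(self, rng, c_in, filters, kernel_w, use_bias=False):
        self.kw = kernel_w
        self.c = c_in
        self.f = filters
        self.use_bias = use_bias
        fan_in = kernel_w * c_in
        self.W = glorot_uniform(rng, (kernel_w, c_in, filters), fan_in, filters)
        self.b = np.zeros(filters, np.float32) if use_bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if use_bias else None

    def params(self):
        return [self.W] + ([self.b] if self.use_bias else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.use_bias else [])

    def forward(self, x, training):
        n, h, w, c = x.shape
        self._xshape = x.shape
        pl = (self.kw - 1) // 2
        nfft = sfft.next_fast_len(w + self.kw - 1, real=True)
        self._nfft, self._pl = nfft, pl
        xs = x.transpose(0, 1, 3, 2).reshape(n * h, c, w)
        self._xhat = sfft.rfft(xs, n=nfft, axis=-1)          # (nh, c, nf)
        # cross-correlation y[t] = sum_k x[t+k-pl] W[k] == conv with
        # reversed kernel, read at offset kw-1-pl
        wrev = self.W[::-1].astype(np.float32)               # (kw, c, f)
        what = sfft.rfft(wrev, n=nfft, axis=0)               # (nf, c, f)
        yhat = np.einsum("xcn,ncf->xfn", self._xhat, what, optimize=True)
        yfull = sfft.irfft(yhat, n=nfft, axis=-1)
        off = self.kw - 1 - pl
        y = yfull[:, :, off:off + w]                          # (nh, f, w)
        y = np.ascontiguousarray(
            y.reshape(n, h, self.f, w).transpose(0, 1, 3, 2)
        )
        if self.use_bias:
            y += self.b
        return y.astype(np.float32)

    def backward(self, dy):
        n, h, w, c = self._xshape
        nfft, pl = self._nfft, self._pl
        dys = dy.transpose(0, 1, 3, 2).reshape(n * h, self.f, w)
        dyhat = sfft.rfft(dys, n=nfft, axis=-1)               # (nh, f, nf)
        if self.use_bias:
            self.db[...] = dy.sum(axis=(0, 1, 2))
        # dW[k] = sum_t x[t+k-pl] dy[t]: circular cross-correlation
        zhat = np.einsum("xcn,xfn->ncf", self._xhat, dyhat.conj(),
                         optimize=True)
        z = sfft.irfft(zhat, n=nfft, axis=0)                  # (nfft, c, f)
        idx = (np.arange(self.kw) - pl) % nfft
        self.dW[...] = z[idx]
        # dx[j] = sum_m dy[m] W[j-m+pl]: linear convolution with W
        what = sfft.rfft(self.W.astype(np.float32), n=nfft, axis=0)
        dxhat = np.einsum("xfn,ncf->xcn", dyhat, what, optimize=True)
        dxfull = sfft.irfft(dxhat, n=nfft, axis=-1)
        dx = dxfull[:, :, pl:pl + w]
        return np.ascontiguousarray(
            dx.reshape(n, h, c, w).transpose(0, 1, 3, 2)
        ).astype(np.float32)


class DepthwiseSpatialConv2D(Layer):
    """(N, H, W, C) -> (N, 1, W, C*D); full-height kernel, valid padding."""

    def __init__(self, rng, h, c_in, depth):
        self.h, self.c, self.d = h, c_in, depth
        self.W = glorot_uniform(rng, (h, c_in, depth), h, depth)
        self.dW = np.zeros_like(self.W)

    def params(self):
        return [self.W]

    def grads(self):
        return [self.dW]

    def forward(self, x, training):
        self._x = x
        n, h, w, c = x.shape
        y = np.einsum("nhwc,hcd->nwcd", x, self.W, optimize=True)
        return np.ascontiguousarray(y).reshape(n, 1, w, c * self.d)

    def backward(self, dy):
        n, _, w, _ = dy.shape
        dy4 = dy.reshape(n, w, self.c, self.d)
        dx = np.empty((n, self.h, w, self.c), np.float32)
        # per-input-channel GEMMs beat one big einsum on these layouts
        for ci in range(self.c):
            xc = np.ascontiguousarray(
                self._x[:, :, :, ci].transpose(1, 0, 2)
            ).reshape(self.h, n * w)                      # (h, n*w)
            dc = np.ascontiguousarray(dy4[:, :, ci, :]).reshape(n * w, self.d)
            self.dW[:, ci, :] = xc @ dc
            dx[:, :, :, ci] = (dc @ self.W[:, ci, :].T).reshape(
                n, w, self.h
            ).transpose(0, 2, 1)
        return dx


class SeparableTemporalConv2D(Layer):
    """Depthwise length-kd temporal conv + pointwise mix; same padding."""

    def __init__(self, rng, c_in, filters, kernel_w):
        self.kd = kernel_w
        self.c = c_in
        self.Wd = glorot_uniform(rng, (kernel_w, c_in), kernel_w, 1)
        self.Wp = glorot_uniform(rng, (c_in, filters), c_in, filters)
        self.dWd = np.zeros_like(self.Wd)
        self.dWp = np.zeros_like(self.Wp)

    def params(self):
        return [self.Wd, self.Wp]

    def grads(self):
        return [self.dWd, self.dWp]

    def forward(self, x, training):
        n, h, w, c = x.shape
        pl, pr = (self.kd - 1) // 2, self.kd // 2
        self._xpad = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        self._xshape = x.shape
        # (n, h, w, c, kd)
        win = _sliding(self._xpad, self.kd, axis=2)
        mid = np.einsum("nhwck,kc->nhwc", win, self.Wd, optimize=True)
        self._mid = mid.reshape(-1, c).astype(np.float32)
        y = self._mid @ self.Wp
        return y.reshape(n, h, w, -1)

    def backward(self, dy):
        n, h, w, c = self._xshape
        f = dy.shape[-1]
        dyf = dy.reshape(-1, f)
        self.dWp[...] = self._mid.T @ dyf
        dmid = (dyf @ self.Wp.T).reshape(n, h, w, c)
        pl, pr = (self.kd - 1) // 2, self.kd // 2
        win = _sliding(self._xpad, self.kd, axis=2)       # (n,h,w,c,kd)
        self.dWd[...] = np.einsum("nhwck,nhwc->kc", win, dmid, optimize=True)
        dxpad = np.zeros_like(self._xpad)
        for k in range(self.kd):
            dxpad[:, :, k:k + w, :] += dmid * self.Wd[k][None, None, None, :]
        return dxpad[:, :, pl:pl + w, :]


class Conv1D(Layer):
    """(N, T, C) -> (N, T, F); same padding, He-uniform init, bias."""

    def __init__(self, rng, c_in, filters, kernel, use_bias=True):
        self.k = kernel
        self.use_bias = use_bias
        self.W = he_uniform(rng, (kernel * c_in, filters), kernel * c_in)
        self.b = np.zeros(filters, np.float32) if use_bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if use_bias else None

    def params(self):
        return [self.W] + ([self.b] if self.use_bias else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.use_bias else [])

    def forward(self, x, training):
        n, t, c = x.shape
        pl, pr = (self.k - 1) // 2, self.k // 2
        xpad = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        cols = _sliding(xpad, self.k, axis=1).transpose(0, 1, 3, 2)
        self._cols = np.ascontiguousarray(cols).reshape(n * t, -1)
        self._xshape = x.shape
        y = self._cols @ self.W
        if self.use_bias:
            y += self.b
        return y.reshape(n, t, -1)

    def backward(self, dy):
        n, t, c = self._xshape
        f = dy.shape[-1]
        dyf = dy.reshape(-1, f)
        self.dW[...] = self._cols.T @ dyf
        if self.use_bias:
            self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(n, t, self.k, c)
        pl, pr = (self.k - 1) // 2, self.k // 2
        dxpad = np.zeros((n, t + pl + pr, c), np.float32)
        for k in range(self.k):
            dxpad[:, k:k + t, :] += dcols[:, :, k, :]
        return dxpad[:, pl:pl + t, :]


class BatchNorm(Layer):
    """Normalize over all axes but the last; Keras-style defaults."""

    def __init__(self, n_features, momentum=0.99, eps=1e-3):
        self.gamma = np.ones(n_features, np.float32)
        self.beta = np.zeros(n_features, np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, np.float32)
        self.running_var = np.ones(n_features, np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        c = x.shape[-1]
        xf = x.reshape(-1, c)
        if training:
            mu = xf.mean(axis=0)
            var = np.einsum("ij,ij->j", xf, xf) / xf.shape[0] - mu * mu
            var = np.maximum(var, 0.0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x * self._inv
        xhat -= (mu * self._inv).astype(np.float32)
        self._xhat = xhat
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        s2 = (dy * self._xhat).sum(axis=axes)
        s1 = dy.sum(axis=axes)
        self.dgamma[...] = s2
        self.dbeta[...] = s1
        m = self._m
        # dx = inv*gamma * (dy - s1/m - xhat*s2/m), fused to 3 passes
        k0 = self._inv * self.gamma
        dx = dy * k0
        dx -= self._xhat * (k0 * (s2 / m))
        dx -= k0 * (s1 / m)
        return dx.astype(np.float32)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self.alpha * self._expm1, x).astype(np.float32)

    def backward(self, dy):
        grad = np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)
        return (dy * grad).astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.005):
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x).astype(np.float32)

    def backward(self, dy):
        return (dy * np.where(self._neg, self.alpha, 1.0)).astype(np.float32)


class AvgPoolW(Layer):
    """Average pooling along axis 2 of (N, H, W, C), floor division."""

    def __init__(self, pool):
        self.p = pool

    def forward(self, x, training):
        n, h, w, c = x.shape
        self._w = w
        w2 = w // self.p
        y = x[:, :, : w2 * self.p, :].reshape(n, h, w2, self.p, c).mean(axis=3)
        return y.astype(np.float32)

    def backward(self, dy):
        n, h, w2, c = dy.shape
        dx = np.zeros((n, h, self._w, c), np.float32)
        dx[:, :, : w2 * self.p, :] = np.repeat(dy / self.p, self.p, axis=2)
        return dx


class MaxPool1D(Layer):
    """Max pooling along axis 1 of (N, T, C), floor division."""

    def __init__(self, pool):
        self.p = pool

    def forward(self, x, training):
        n, t, c = x.shape
        self._t = t
        t2 = t // self.p
        blocks = x[:, : t2 * self.p, :].reshape(n, t2, self.p, c)
        self._arg = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, dy):
        n, t2, c = dy.shape
        dx = np.zeros((n, t2, self.p, c), np.float32)
        n_i, t_i, c_i = np.ogrid[:n, :t2, :c]
        dx[n_i, t_i, self._arg, c_i] = dy
        dx = dx.reshape(n, t2 * self.p, c)
        if t2 * self.p < self._t:
            dx = np.pad(dx, ((0, 0), (0, self._t - t2 * self.p), (0, 0)))
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32)
        self._mask /= keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, rng, n_in, n_out, use_bias=True):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, np.float32) if use_bias else None
        self.use_bias = use_bias
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if use_bias else None

    def params(self):
        return [self.W] + ([self.b] if self.use_bias else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.use_bias else [])

    def forward(self, x, training):
        self._x = x
        y = x @ self.W
        if self.use_bias:
            y += self.b
        return y

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        if self.use_bias:
            self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class LSTM(Layer):
    """Standard-gate LSTM (input/forget/cell/output, bias, no peepholes).

    ``return_sequences`` emits the full hidden sequence (N, T, U); otherwise
    the final hidden state (N, U).  Forget-gate bias initialized to 1.
    """

    def __init__(self, rng, c_in, units, return_sequences):
        u = units
        self.u = u
        self.return_sequences = return_sequences
        self.Wx = glorot_uniform(rng, (c_in, 4 * u), c_in, 4 * u)
        # orthogonal recurrent init, one block per gate
        self.Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((u, u)))[0] for _ in range(4)],
            axis=1,
        ).astype(np.float32)
        self.b = np.zeros(4 * u, np.float32)
        self.b[u:2 * u] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, training):
        n, t, c = x.shape
        u = self.u
        self._x = x
        h = np.zeros((n, u), np.float32)
        cs = np.zeros((n, u), np.float32)
        self._cache = []
        hs = np.empty((n, t, u), np.float32)
        xz = np.einsum("ntc,cg->ntg", x, self.Wx, optimize=True) + self.b
        for step in range(t):
            z = xz[:, step, :] + h @ self.Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev = cs
            cs = f * c_prev + i * g
            tanh_c = np.tanh(cs)
            h_prev = h
            h = o * tanh_c
            hs[:, step, :] = h
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        n, t, c = x.shape
        u = self.u
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u), np.float32)
        dc_next = np.zeros((n, u), np.float32)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, step, :]
            elif step == t - 1:
                dh += dy
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1).astype(np.float32)
            self.dWx += x[:, step, :].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx
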