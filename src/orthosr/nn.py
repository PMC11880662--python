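"""Minimal 3D convolutional network engine on numpy.

Implements exactly the pieces the super-resolution network needs — 'same'
3x3x3 and 1x1x1 convolutions, per-channel batch normalisation, ELU, and Adam —
with hand-written backward passes.  Convolutions are evaluated tap-by-tap as
27 BLAS matmuls over the channel dimension, which keeps peak memory at one
(N, C, D*H*W) buffer and runs at GEMM speed on a single CPU.

Tensors are ``(N, C, D, H, W)`` float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "BatchNorm3d", "ELU", "Adam"]

_TAPS3 = [(i, j, l) for i in range(3) for j in range(3) for l in range(3)]


class Conv3d:
    """'Same' 3D convolution with kernel size 1 or 3, zero padding, bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, scale: float | None = None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        fan_in = in_channels * kernel**3
        if scale is None:
            scale = np.sqrt(2.0 / fan_in)  # He init (ELU-friendly)
        self.kernel = kernel
        self.W = rng.normal(0.0, scale, (out_channels, in_channels,
                                         kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, D, H, W = x.shape
        O = self.W.shape[0]
        if self.kernel == 1:
            out = np.matmul(self.W[:, :, 0, 0, 0], x.reshape(N, C, -1))
            out = out.reshape(N, O, D, H, W)
        else:
            # tap-by-tap: 27 channel-mixing GEMMs on contiguous slabs keeps
            # locality high and peak memory at one (N, C, M) buffer
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            acc = np.zeros((N, O, D * H * W), dtype=np.float32)
            for i, j, l in _TAPS3:
                xs = np.ascontiguousarray(
                    xp[:, :, i:i + D, j:j + H, l:l + W]).reshape(N, C, -1)
                acc += np.matmul(self.W[:, :, i, j, l], xs)
            out = acc.reshape(N, O, D, H, W)
        out += self.b[None, :, None, None, None]
        if train:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        N, C, D, H, W = x.shape
        O = self.W.shape[0]
        dflat = dout.reshape(N, O, -1)
        self.db += dout.sum(axis=(0, 2, 3, 4))
        if self.kernel == 1:
            xf = x.reshape(N, C, -1)
            self.dW[:, :, 0, 0, 0] += np.einsum("nom,ncm->oc", dflat, xf)
            dx = np.matmul(self.W[:, :, 0, 0, 0].T, dflat).reshape(x.shape)
            return dx
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        for i, j, l in _TAPS3:
            xs = np.ascontiguousarray(
                xp[:, :, i:i + D, j:j + H, l:l + W]).reshape(N, C, -1)
            self.dW[:, :, i, j, l] += np.matmul(dflat, xs.transpose(0, 2, 1)
                                                ).sum(axis=0)
            dxs = np.matmul(self.W[:, :, i, j, l].T, dflat)
            dxp[:, :, i:i + D, j:j + H, l:l + W] += dxs.reshape(N, C, D, H, W)
        return dxp[:, :, 1:-1, 1:-1, 1:-1]

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm3d:
    """Per-channel batch normalisation with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        sh = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        out = self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)
        if train:
            self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        sh = (1, -1, 1, 1, 1)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.dbeta += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma.reshape(sh)
        dx = (inv.reshape(sh) / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3, 4)).reshape(sh)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3, 4)).reshape(sh)
        )
        return dx.astype(np.float32)


class ELU:
    """Exponential linear unit, alpha = 1."""

    n_params = 0

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))).astype(np.float32)
        if train:
            self._cache = (x > 0, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        return np.where(pos, dout, dout * (out + 1.0)).astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of (array, grad) pairs."""

    def __init__(self, param_grads, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.param_grads = list(param_grads)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.param_grads]
        self.v = [np.zeros_like(p) for p, _ in self.param_grads]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for i, (p, g) in enumerate(self.param_grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.param_grads:
            g[...] = 0.0
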