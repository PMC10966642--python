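"""Layer primitives operating on (batch, length, channels) float32 arrays.

Convolutions use "same"-style padding so lengths halve/double exactly
with stride 2.  Every layer caches what its backward pass needs; backward
returns the gradient with respect to the layer input and accumulates
parameter gradients in-place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv1d", "ConvTranspose1d", "BatchNorm1d",
           "LeakyReLU", "ReLU", "Tanh", "Dropout"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self):
        return []

    def state_arrays(self):
        """All arrays needed to restore the layer (params + buffers)."""
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays):
        own = self.state_arrays()
        if len(arrays) != len(own):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class Conv1d(Layer):
    """1-D convolution, stride ``s``, same padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, std, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, _ = x.shape
        s, k = self.stride, self.k
        L_out = -(-L // s)
        pad = max((L_out - 1) * s + k - L, 0)
        pl = pad // 2
        x_pad = np.pad(x, ((0, 0), (pl, pad - pl), (0, 0)))
        y = np.broadcast_to(self.b.value, (B, L_out, self.c_out)).copy()
        W = self.W.value
        for j in range(k):
            xs = x_pad[:, j:j + s * (L_out - 1) + 1:s, :]
            y += xs @ W[j]
        self._cache = (x_pad, L, pl, L_out)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_pad, L, pl, L_out = self._cache
        s, k = self.stride, self.k
        gx_pad = np.zeros_like(x_pad)
        W = self.W.value
        for j in range(k):
            sl = slice(j, j + s * (L_out - 1) + 1, s)
            xs = x_pad[:, sl, :]
            self.W.grad[j] += np.einsum("blc,bld->cd", xs, gy, optimize=True)
            gx_pad[:, sl, :] += gy @ W[j].T
        self.b.grad += gy.sum(axis=(0, 1))
        return gx_pad[:, pl:pl + L, :]


class ConvTranspose1d(Layer):
    """Transposed 1-D convolution (length multiplied by the stride)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel < stride:
            raise ValueError("kernel must be >= stride")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, std, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, _ = x.shape
        s, k = self.stride, self.k
        L_out = L * s
        L_full = (L - 1) * s + k
        start = (k - s) // 2
        full = np.zeros((B, L_full, self.c_out), dtype=x.dtype)
        W = self.W.value
        for j in range(k):
            full[:, j:j + s * (L - 1) + 1:s, :] += x @ W[j]
        y = full[:, start:start + L_out, :] + self.b.value
        self._cache = (x, L, L_full, start, L_out)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, L, L_full, start, L_out = self._cache
        s, k = self.stride, self.k
        gfull = np.zeros((gy.shape[0], L_full, self.c_out), dtype=gy.dtype)
        gfull[:, start:start + L_out, :] = gy
        gx = np.zeros_like(x)
        W = self.W.value
        for j in range(k):
            gs = gfull[:, j:j + s * (L - 1) + 1:s, :]
            self.W.grad[j] += np.einsum("blc,bld->cd", x, gs, optimize=True)
            gx += gs @ W[j].T
        self.b.grad += gy.sum(axis=(0, 1))
        return gx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.value, self.beta.value, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape[0] * x.shape[1], training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, N, training = self._cache
        dgamma = np.einsum("blc,blc->c", gy, xhat, optimize=True)
        dbeta = gy.sum(axis=(0, 1))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if not training:
            return gy * (self.gamma.value * inv)
        return (self.gamma.value * inv / N) * (N * gy - dbeta - xhat * dgamma)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2):
        self.slope = negative_slope

    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class ReLU(Layer):
    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Tanh(Layer):
    def forward(self, x, training: bool = False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y * self._y)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training: bool = False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask
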