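"""Minimal dense/3D-convolutional layers with exact manual backprop.

Only what the Siamese trainer needs: non-overlapping (kernel == stride)
3D convolutions, ReLU, global average pooling, dense layers, and Adam with
a step-decay learning-rate schedule. Non-overlapping convolutions make the
backward pass a pure reshape/matmul, which keeps CPU training fast and the
gradients exactly checkable against finite differences.

All layers are stateless across calls: ``forward`` returns ``(out, cache)``
and ``backward(dout, cache)`` returns the input gradient while accumulating
parameter gradients, so one set of weights can be applied to both slots of
a Siamese pair and receive the summed gradient.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A weight tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (out, cache)
        raise NotImplementedError

    def backward(self, dout: np.ndarray, cache):  # -> dx
        raise NotImplementedError


class PatchConv3d(Layer):
    """3D convolution with kernel == stride (non-overlapping patches).

    Input (B, C_in, D, H, W) with all spatial dims divisible by ``k``;
    output (B, C_out, D/k, H/k, W/k).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        fan_in = c_in * k**3
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.w, self.b]

    def _patchify(self, x):
        b, c, d, h, w = x.shape
        k = self.k
        if c != self.c_in or d % k or h % k or w % k:
            raise ValueError(f"input shape {x.shape} incompatible with k={k}, c_in={self.c_in}")
        x = x.reshape(b, c, d // k, k, h // k, k, w // k, k)
        x = x.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # (B, D', H', W', C, k, k, k)
        return x.reshape(b, (d // k) * (h // k) * (w // k), c * k**3), (d // k, h // k, w // k)

    def forward(self, x):
        patches, spatial = self._patchify(x)
        out = patches @ self.w.value.T + self.b.value  # (B, P, C_out)
        b = x.shape[0]
        out = out.transpose(0, 2, 1).reshape(b, self.c_out, *spatial)
        return out, (patches, spatial, x.shape)

    def backward(self, dout, cache):
        patches, spatial, x_shape = cache
        b = dout.shape[0]
        dflat = dout.reshape(b, self.c_out, -1).transpose(0, 2, 1)  # (B, P, C_out)
        self.w.grad += np.einsum("bpo,bpf->of", dflat, patches)
        self.b.grad += dflat.sum(axis=(0, 1))
        dpatches = dflat @ self.w.value  # (B, P, C_in*k^3)
        k = self.k
        dp, hp, wp = spatial
        dx = dpatches.reshape(b, dp, hp, wp, self.c_in, k, k, k)
        dx = dx.transpose(0, 4, 1, 5, 2, 6, 3, 7)
        return dx.reshape(x_shape)


class ReLU(Layer):
    """Leaky rectifier; a small negative slope keeps units recoverable."""

    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope

    def forward(self, x):
        scale = np.where(x > 0, 1.0, self.negative_slope)
        return x * scale, scale

    def backward(self, dout, cache):
        return dout * cache


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C), averaging over the spatial axes."""

    def forward(self, x):
        return x.mean(axis=(2, 3, 4)), x.shape

    def backward(self, dout, cache):
        b, c, d, h, w = cache
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            dout[:, :, None, None, None], cache
        ) * scale


class Flatten(Layer):
    """(B, C, D, H, W) -> (B, C*D*H*W); keeps spatial location information."""

    def forward(self, x):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dout, cache):
        return dout.reshape(cache)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        return x @ self.w.value.T + self.b.value, x

    def backward(self, dout, cache):
        self.w.grad += dout.T @ cache
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, dout, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dout = layer.backward(dout, cache)
        return dout


class Adam:
    """Adam with a step-decay learning-rate schedule (lr * gamma^(epoch // every))."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def set_epoch(self, epoch: int, gamma: float, decay_every: int) -> None:
        """Set the learning rate for a 1-based epoch index."""
        self.lr = self.base_lr * gamma ** ((epoch - 1) // decay_every)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_weights(net: Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(net.params(), weights):
        p.value[...] = w
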